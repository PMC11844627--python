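"""MitoCarta3.0 pathway annotations.

MitoCarta3.0 distributes a curated inventory of mitochondrial genes together
with 149 functional pathways ("MitoPathways") organized on three nested
levels, e.g. ``OXPHOS > Complex I > CI subunits``. A gene may belong to
several pathways, and a parent pathway's gene list contains every gene of its
children. This module parses the pathway and gene sheets (XLSX or TSV) into a
queryable :class:`PathwayHierarchy`, harmonizes input gene symbols against the
MitoCarta symbol space, and restricts expression matrices to mitochondrial
genes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "PathwayNode",
    "PathwayHierarchy",
    "AliasTable",
    "SymbolReport",
    "SubsetReport",
    "load_mitocarta",
    "resolve_symbols",
    "mito_subset",
]

HIERARCHY_SEP = " > "


class AnnotationParseError(ValueError):
    """Malformed pathway annotation input."""


class StructuralError(ValueError):
    """Hierarchy violates the 3-level nesting contract."""


@dataclass
class PathwayNode:
    """One pathway: full hierarchical path id, display name, level, genes."""

    id: str
    name: str
    level: int
    parent_id: str | None
    genes: frozenset[str]


@dataclass
class PathwayHierarchy:
    nodes: list[PathwayNode]
    gene_universe: frozenset[str]
    species: str = "human"

    def __post_init__(self) -> None:
        self._by_id = {n.id: n for n in self.nodes}
        if len(self._by_id) != len(self.nodes):
            raise StructuralError("duplicate pathway ids")

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, pathway_id: str) -> PathwayNode:
        return self._by_id[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def children(self, pathway_id: str) -> list[PathwayNode]:
        return [n for n in self.nodes if n.parent_id == pathway_id]

    def at_level(self, level: int) -> list[PathwayNode]:
        return [n for n in self.nodes if n.level == level]

    def leaves(self) -> list[PathwayNode]:
        has_child = {n.parent_id for n in self.nodes if n.parent_id}
        return [n for n in self.nodes if n.id not in has_child]

    def validate(self) -> None:
        """Check nesting and gene-containment invariants; raise on violation."""
        for node in self.nodes:
            if node.level == 1:
                if node.parent_id is not None:
                    raise StructuralError(f"level-1 pathway {node.id!r} has a parent")
            else:
                if node.parent_id is None or node.parent_id not in self._by_id:
                    raise StructuralError(
                        f"orphan level-{node.level} pathway {node.id!r}"
                    )
                parent = self._by_id[node.parent_id]
                if parent.level != node.level - 1:
                    raise StructuralError(
                        f"pathway {node.id!r} (level {node.level}) has parent of "
                        f"level {parent.level}"
                    )
                if not node.genes <= parent.genes:
                    missing = sorted(node.genes - parent.genes)[:5]
                    raise StructuralError(
                        f"parent {parent.id!r} is missing child genes {missing}"
                    )
            if not node.genes:
                raise StructuralError(f"pathway {node.id!r} has an empty gene set")
            if not node.genes <= self.gene_universe:
                raise StructuralError(
                    f"pathway {node.id!r} lists genes outside the gene universe"
                )

    def gene_count_table(self) -> pd.DataFrame:
        """Per-pathway gene counts (the loader's summary report)."""
        return pd.DataFrame(
            {
                "pathway": [n.id for n in self.nodes],
                "level": [n.level for n in self.nodes],
                "n_genes": [len(n.genes) for n in self.nodes],
            }
        ).set_index("pathway")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "gene_universe": sorted(self.gene_universe),
            "nodes": [
                {
                    "id": n.id,
                    "name": n.name,
                    "level": n.level,
                    "parent_id": n.parent_id,
                    "genes": sorted(n.genes),
                }
                for n in self.nodes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayHierarchy":
        payload = json.loads(Path(path).read_text())
        nodes = [
            PathwayNode(
                id=d["id"],
                name=d["name"],
                level=int(d["level"]),
                parent_id=d["parent_id"],
                genes=frozenset(d["genes"]),
            )
            for d in payload["nodes"]
        ]
        return cls(
            nodes=nodes,
            gene_universe=frozenset(payload["gene_universe"]),
            species=payload["species"],
        )


# The 13 mtDNA-encoded protein genes are sometimes distributed without their
# "MT-" prefix (e.g. ND1 for MT-ND1); restoring the prefix is an ordered
# rewrite rule rather than a plain lookup so the table stays idempotent.
_MTDNA_STEMS = frozenset(
    {
        "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
        "CO1", "CO2", "CO3", "ATP6", "ATP8", "CYB",
    }
)

_DEFAULT_SYNONYMS = {"C12orf10": "MYG1"}


@dataclass
class AliasTable:
    """Ordered symbol-rewrite rules followed by a synonym lookup.

    Two rules ship by default: restore the "MT-" prefix on bare mtDNA gene
    stems, and map C12orf10 to its synonym MYG1. Extra synonyms can be loaded
    from a two-column TSV (raw, canonical). The table is idempotent:
    resolve(resolve(s)) == resolve(s).
    """

    mapping: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_SYNONYMS))
    mt_prefix: bool = True

    def __post_init__(self) -> None:
        for raw, canonical in self.mapping.items():
            if self.resolve(canonical) != canonical:
                raise ValueError(
                    f"alias target {canonical!r} (for {raw!r}) is not canonical; "
                    "the table would not be idempotent"
                )

    def resolve(self, symbol: str) -> str:
        if self.mt_prefix and symbol in _MTDNA_STEMS:
            symbol = "MT-" + symbol
        return self.mapping.get(symbol, symbol)

    def extend_from_file(self, path: str | Path) -> "AliasTable":
        extra = pd.read_csv(path, sep="\t", header=None, names=["raw", "canonical"])
        merged = dict(self.mapping)
        merged.update(dict(zip(extra["raw"].astype(str), extra["canonical"].astype(str))))
        return AliasTable(mapping=merged, mt_prefix=self.mt_prefix)


@dataclass
class SymbolReport:
    resolved: dict[str, str]
    unmapped: list[str]


@dataclass
class SubsetReport:
    n_found: int
    missing_from_input: list[str]
    renamed: dict[str, str]


def _read_table(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _find_column(df: pd.DataFrame, *needles: str) -> str | None:
    for needle in needles:
        for col in df.columns:
            if needle in str(col).lower():
                return col
    return None


def load_mitocarta(
    pathway_file: str | Path,
    species: str = "human",
    gene_file: str | Path | None = None,
    sheet: str | int | None = None,
) -> PathwayHierarchy:
    """Parse a MitoCarta3.0 pathway sheet into a :class:`PathwayHierarchy`.

    Expects one row per pathway with a hierarchy label (segments joined by
    ``>``) and a comma-separated gene list; accepts both the XLSX sheet as
    distributed and TSV/CSV exports of it. When ``gene_file`` (the MitoCarta
    gene sheet, one row per gene with a Symbol column) is given, its symbols
    define the gene universe; otherwise the universe is the union of all
    pathway gene lists.
    """
    df = _read_table(pathway_file, sheet=sheet)
    hier_col = _find_column(df, "hierarchy")
    genes_col = _find_column(df, "genes")
    name_col = _find_column(df, "mitopathway", "pathway", "name")
    if hier_col is None or genes_col is None:
        raise AnnotationParseError(
            f"pathway file {pathway_file} needs a hierarchy column and a genes "
            f"column; found columns {list(df.columns)}"
        )

    hier_pos = df.columns.get_loc(hier_col)
    genes_pos = df.columns.get_loc(genes_col)
    name_pos = df.columns.get_loc(name_col) if name_col is not None else None

    nodes: list[PathwayNode] = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        label = str(row[hier_pos]).strip()
        if not label or label.lower() == "nan":
            raise AnnotationParseError(f"row {row_num}: empty hierarchy label")
        segments = [s.strip() for s in label.split(">")]
        if not all(segments) or len(segments) > 3:
            raise AnnotationParseError(
                f"row {row_num}: malformed hierarchy label {label!r}"
            )
        raw_genes = row[genes_pos]
        gene_list = [] if pd.isna(raw_genes) else [
            g.strip() for g in str(raw_genes).split(",") if g.strip()
        ]
        name = segments[-1]
        if name_pos is not None:
            declared = str(row[name_pos]).strip()
            if declared and declared.lower() != "nan":
                name = declared
        nodes.append(
            PathwayNode(
                id=HIERARCHY_SEP.join(segments),
                name=name,
                level=len(segments),
                parent_id=HIERARCHY_SEP.join(segments[:-1]) or None,
                genes=frozenset(gene_list),
            )
        )

    if gene_file is not None:
        gdf = _read_table(gene_file)
        sym_col = _find_column(gdf, "symbol")
        if sym_col is None:
            raise AnnotationParseError(
                f"gene file {gene_file} has no symbol column"
            )
        universe = frozenset(gdf[sym_col].dropna().astype(str).str.strip())
    else:
        universe = frozenset().union(*(n.genes for n in nodes)) if nodes else frozenset()

    hierarchy = PathwayHierarchy(nodes=nodes, gene_universe=universe, species=species)
    hierarchy.validate()
    return hierarchy


def resolve_symbols(
    symbols: list[str],
    aliases: AliasTable,
    hierarchy: PathwayHierarchy,
) -> SymbolReport:
    """Map raw symbols into the hierarchy's gene universe; report the rest.

    Every input is accounted for: either resolved (possibly to itself) or
    listed as unmapped. Unmapped symbols are a report, not an error — an
    expression matrix legitimately contains non-mitochondrial genes.
    """
    resolved: dict[str, str] = {}
    unmapped: list[str] = []
    for symbol in symbols:
        canonical = aliases.resolve(symbol)
        if canonical in hierarchy.gene_universe:
            resolved[symbol] = canonical
        else:
            unmapped.append(symbol)
    return SymbolReport(resolved=resolved, unmapped=unmapped)


def mito_subset(
    expr: ExpressionMatrix,
    hierarchy: PathwayHierarchy,
    aliases: AliasTable | None = None,
) -> tuple[ExpressionMatrix, SubsetReport]:
    """Restrict an expression matrix to MitoCarta genes.

    Row symbols are first harmonized through the alias table, then
    intersected with the gene universe. The report lists universe genes
    absent from the input (pathway coverage downstream depends on them).
    Finding zero mitochondrial genes is a hard error — it almost always
    means the matrix is keyed by another identifier space (e.g. Ensembl ids).
    """
    aliases = aliases or AliasTable()
    report = resolve_symbols(list(expr.genes), aliases, hierarchy)
    if not report.resolved:
        raise ValueError(
            "no mitochondrial genes found in the expression matrix; are the "
            "rows keyed by gene symbol?"
        )
    keep = list(report.resolved)
    sub = expr.values.loc[keep].copy()
    sub.index = [report.resolved[g] for g in keep]
    if sub.index.duplicated().any():
        dup = sub.index[sub.index.duplicated()].unique().tolist()
        raise ValueError(f"alias resolution merged distinct input genes: {dup}")
    renamed = {raw: canon for raw, canon in report.resolved.items() if raw != canon}
    missing = sorted(hierarchy.gene_universe - set(sub.index))
    out = ExpressionMatrix(
        values=sub,
        unit=expr.unit,
        provenance=expr.provenance + "|mito_subset",
    )
    return out, SubsetReport(
        n_found=sub.shape[0], missing_from_input=missing, renamed=renamed
    )
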