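from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mitotyper import ExpressionMatrix, load_mitocarta

DATA = Path(__file__).parent / "data"


def naive_mitopps(scores: pd.DataFrame, reference: list | None = None) -> pd.DataFrame:
    """Literal triple-loop evaluation of the prioritization-score double sum.

    Independent oracle: no vectorization, no shared code with the production
    implementation.
    """
    pathways = list(scores.index)
    samples = list(scores.columns)
    ref = samples if reference is None else list(reference)
    out = pd.DataFrame(index=pathways, columns=samples, dtype=float)
    for si in samples:
        for pi in pathways:
            total = 0.0
            for pn in pathways:
                if pn == pi:
                    continue
                ratio = scores.loc[pi, si] / scores.loc[pn, si]
                denom = 0.0
                for sx in ref:
                    denom += scores.loc[pi, sx] / scores.loc[pn, sx]
                denom /= len(ref)
                total += ratio / denom
            out.loc[pi, si] = total / (len(pathways) - 1)
    return out


@pytest.fixture(scope="session")
def mini_pathway_file() -> Path:
    return DATA / "mini_pathways.tsv"


@pytest.fixture(scope="session")
def mini_hier(mini_pathway_file):
    return load_mitocarta(mini_pathway_file, species="human")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def random_scores(rng) -> pd.DataFrame:
    """Strictly positive 10-pathway x 6-sample score matrix."""
    return pd.DataFrame(
        rng.lognormal(0.0, 1.0, (10, 6)),
        index=[f"P{i}" for i in range(10)],
        columns=[f"S{j}" for j in range(6)],
    )


@pytest.fixture()
def mini_expr(mini_hier, rng) -> ExpressionMatrix:
    """Positive expression over the miniature hierarchy's 30 genes, 5 samples."""
    genes = sorted(mini_hier.gene_universe)
    values = pd.DataFrame(
        rng.lognormal(2.0, 0.8, (len(genes), 5)),
        index=genes,
        columns=[f"T{j}" for j in range(5)],
    )
    return ExpressionMatrix(values=values, unit="nTPM")
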