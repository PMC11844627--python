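# mitotyper

Quantify mitochondrial specialization ("mitotyping") from bulk
transcriptomic or proteomic expression matrices.

Mitochondria are not interchangeable: liver mitochondria run urea cycle and
fatty-acid oxidation programs that brain mitochondria barely express, while
the brain overexpresses Complex I relative to the rest of the electron
transport chain. `mitotyper` turns a gene × sample expression matrix into
interpretable, pathway-level summaries of that specialization, using the
MitoCarta3.0 inventory of 149 mitochondrial pathways arranged in a 3-level
hierarchy. It is aimed at mitochondrial biologists and bioinformaticians
working with bulk RNA-seq (counts or nTPM), tissue-consensus atlases, or
proteomics intensity matrices.

## The two core quantities

**MitoPathway score.** For pathway *P* and sample *S*, the score is the
arithmetic mean expression of *P*'s member genes present in the matrix:

    Score(S, P) = mean{ expr(g, S) : g ∈ genes(P) }

Scores inherit the input unit and are comparable *between samples* for one
pathway, but they are confounded by overall mitochondrial content: a sample
with more mitochondria scores higher on every pathway.

**Mitochondrial Pathway Prioritization Score (mitoPPS).** The
content-independent quantity. With n′ pathways and a reference set of x′
samples,

    mitoPPS(Si, Pi) = 1/(n′−1) · Σ_{Pn ≠ Pi}
        [ Score(Si,Pi)/Score(Si,Pn) ]
        / [ 1/x′ · Σ_{Sx} Score(Sx,Pi)/Score(Sx,Pn) ]

i.e. every within-sample pathway ratio is normalized by that ratio's mean
across the reference samples, then averaged over partner pathways. 1.0 is
average priority; 2.1 means the sample invests ~110% extra in the pathway,
0.35 means −65%. Because each term is a within-sample ratio, multiplying a
sample's expression by any positive constant changes nothing — the
mitochondrial-content bias cancels exactly — and with the whole dataset as
reference the per-pathway mean over samples is exactly 1. The reference can
instead be a control group (untreated/healthy samples), turning the score
into prioritization relative to controls.

Around these two quantities the package provides: MitoCarta3.0 annotation
parsing and gene-symbol harmonization, readers for GCT / long-consensus /
delimited matrices, TMM library-size normalization and half-minimum
imputation, PCA, Ward.D2 and k-means clustering, Spearman correlation
networks, a gate-driven two-group test decision tree
(Shapiro-Wilk + Fligner-Killeen → Student / Welch / Wilcoxon /
Brunner-Munzel) with Hedges' g, and a synthetic-data generator with planted
ground truth.

## Worked example

Plant a 2× prioritization of one pathway in half of a synthetic cohort and
recover it:

```python
from mitotyper import (SyntheticConfig, generate, score_pathways,
                       compute_mitopps, prioritization_percent, compare_groups)

plant = "Branch1 > Module1 > Leaf1"
cfg = SyntheticConfig(seed=42, n_samples=40, n_groups=2, noise_sigma=0.1,
                      priorities={"group1": {plant: 2.0}})
matrix, hierarchy, samples, truth = generate(cfg)

scores = score_pathways(matrix, hierarchy)          # 12 pathways x 40 samples
pps = compute_mitopps(scores.values)                # reference = all samples

g1 = list(samples.index[samples["group"] == "group1"])
g2 = list(samples.index[samples["group"] == "group2"])
print(round(pps.values.loc[plant, g1].mean(), 3))   # 1.305
print(round(pps.values.loc[plant, g2].mean(), 3))   # 0.695
print(round(prioritization_percent(pps).loc[plant, g1].mean(), 1))  # 30.5
res = compare_groups(pps.values.loc[plant, g1], pps.values.loc[plant, g2])
print(res.test, f"{res.p_value:.2e}", round(res.hedges_g, 2))
# welch_t 1.61e-30 20.04
```

The planted group averages mitoPPS 1.305 for the planted pathway (+30.5%
priority) and the unplanted group 0.695: with the whole cohort as reference
the scores straddle 1 while their per-pathway mean over all 40 samples stays
exactly 1. The gate tests route the contrast to Welch's t (normal groups,
unequal variances), which separates the groups decisively.

The same pipeline runs from the shell:

```bash
mitotyper simulate --out-dir sim/ --seed 7
mitotyper score --expr sim/matrix.tsv --mitocarta sim/hierarchy.json \
                --unit intensity --out scores.tsv
mitotyper mitopps --scores scores.tsv --out mitopps.tsv
```

For real data, `mitotyper normalize` TMM-scales raw counts (GCT or TSV),
`mitotyper impute` handles proteomics missingness, and `mitotyper atlas`
reproduces the multi-tissue summary numbers from local copies of a
tissue-consensus expression table and the MitoCarta3.0 pathway sheet (it
never downloads anything).

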