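# sigratio

Gene-signature correlation-ratio scoring and companion analyses for
brain-tumor transcriptomics.

Malignant brain tumors (medulloblastoma, glioblastoma) suppress innate
immunity partly through the CD24/Siglec-10 "don't eat me" axis: CD24 on
tumor cells engages the inhibitory receptor Siglec-10 on tumor-associated
macrophages and microglia (TAMs). A practical way to ask whether a gene of
interest tracks tumor cells or a particular TAM phenotype in bulk
expression cohorts is to correlate it with small curated gene signatures
and summarize how much of each signature it recruits. `sigratio`
implements that analysis end to end, together with the enrichment-based
subtype caller, survival statistics and fluorescence-image quantification
used alongside it, and synthetic-data generators with known ground truth
so every stage is testable without any cohort download.

## The core statistic

For a gene of interest *g* and a signature *S* of *m* genes, compute the
Spearman rank correlation ρ (with midrank tie handling and a two-sided
p-value, exact by permutation enumeration for small n) between *g* and
each signature gene, then classify each pair on a seven-level tier scale:

| tier | requirement |
|---|---|
| weak (±) | \|ρ\| ≥ 0.26 and p < 0.001 |
| moderate (±) | \|ρ\| ≥ 0.30 and p < 0.05 |
| strong (±) | \|ρ\| ≥ 0.50 and p < 0.05 |

The strongest satisfied tier wins; r cutoffs are inclusive, p cutoffs
strict. The **ratio score** is

  ratio = (# signature genes reaching any tier of the matching sign) / d,

where the denominator *d* = *m* − (genes absent from the platform) −
(1 if *g* is itself a signature member). With the built-in 10-gene
high-risk signature this reproduces the published divide-by-10 rule and
its adjustments: divide by 8 when two genes are platform-missing, by 11
when IDO1 is absent from the 12-gene M1 panel, and by 11 when TREM2 is
scored against the 12-gene M2 panel that contains it.

Also included:

* `gsea` — preranked enrichment (weighted Kolmogorov–Smirnov running sum),
  gene-tag permutation NES, and per-sample subtype assignment by maximum
  NES across subtype gene sets (GMT input).
* `rankstats` — midranks, Spearman, Mann–Whitney U (exact/normal),
  Kaplan–Meier and the two-group log-rank (Mantel–Cox) test, written from
  first principles and cross-checked against scipy/lifelines in the tests.
* `survival` — horizon-censored survival comparison and MTT viability
  normalization (OD540 − OD650, scaled to the untreated mean) with a
  log-dose interpolated 50%-viability crossing.
* `imaging` — DAPI tumor masks with areas in mm², stained-area/tumor-area
  ratios under a fixed shared threshold, watershed nucleus counting, and
  stain-per-nucleus readouts.
* `simulate` — Gaussian-copula expression matrices with planted Spearman
  correlations, exponential survival with administrative censoring,
  two-channel stain images, and subtype panels — all pure functions of
  their seed, with exact ground truth returned.

## Worked example

```python
from sigratio.simulate import ExpressionSimSpec, simulate_expression
from sigratio.signatures import HIGH_RISK
from sigratio.scoring import ratio_score

spec = ExpressionSimSpec("CD24", HIGH_RISK, n_samples=200,
                         planted_rho=0.6, n_planted=7, seed=42)
expr, truth = simulate_expression(spec)
score = ratio_score(expr, "CD24", HIGH_RISK, direction="positive")
print(f"ratio = {score.numerator}/{score.denominator} = {score.ratio}")
```

prints

```
ratio = 7/10 = 0.7
```

— seven of the ten high-risk genes were planted at Spearman ρ = 0.6 with
CD24 in 200 samples, and the scorer recovers exactly those seven
(`truth.planted_genes` lists them). A survival comparison looks like:

```python
from sigratio.simulate import simulate_survival
from sigratio.survival import compare_survival

recs = simulate_survival({"control": 28, "mtx": 17},
                         {"control": 0.05, "mtx": 0.025}, 100.0, seed=42)
comp = compare_survival(recs, "control", "mtx")
print(f"log-rank chi2 = {comp.test.statistic:.3f}, p = {comp.test.p_two_sided:.4f}")
```

```
log-rank chi2 = 1.362, p = 0.2432
```

with `comp.medians` giving each group's Kaplan–Meier median (first time
the survival curve drops to 0.5 or below).

The same workflows are exposed on the command line (`sigratio --help`):
`score-signature`, `tam-profile`, `tier-table`, `subtype`, `survival`,
`viability`, `quantify-image` and the `simulate-*` generators, all
seeded and deterministic.

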