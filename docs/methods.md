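# Methods

This note documents the statistical procedures `sigratio` implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Correlation tiers and the ratio score

The tier scale classifies a Spearman (ρ, p) pair into weak / moderate /
strong, positive / negative, or none. The published cutoffs are taken
literally: r thresholds are inclusive (≥ 0.26, ≥ 0.30, ≥ 0.50 in
magnitude), p thresholds strict (< 0.001 for weak, < 0.05 for moderate
and strong), and when several tiers' conditions hold the strongest wins
(the published color scale is mutually exclusive). A consequence of the
literal reading is a gap: pairs with |ρ| ∈ [0.26, 0.30) and
p ∈ [0.001, 0.05) classify as "none". We keep that behavior as the
default and expose `ClassificationThresholds.relaxed_weak()` (CLI
`--relax-weak`) for sensitivity analyses that close the gap by relaxing
the weak tier's p cutoff to 0.05.

The ratio score counts signature genes whose tier sign matches the
requested direction — a negative correlation never counts toward a
positive-direction score, matching the separate positive/negative report
panels the signatures were designed for. The denominator is
|signature| − |platform-missing genes| − (1 if the gene of interest is a
signature member). The published rules state three instances (÷8 for two
missing genes in a 10-gene signature, ÷11 for one missing gene in a
12-gene signature, ÷11 for self-membership in a 12-gene signature); we
generalize to any number of missing genes and apply self-exclusion for
every signature, not only the one published case, always reporting the
adjustment in the result. A signature gene with zero expression variance
has no defined correlation; it classifies as "none" but keeps its
denominator slot, since it was measurable on the platform.

Two registry symbols ("ITGB", "ZPF3") are not standard HGNC symbols but
are kept verbatim; on real platforms they register as missing and the
denominator adjustment absorbs them.

## Rank statistics

These primitives are written from first principles because the analysis
rests on them; scipy supplies only reference-distribution tail
probabilities, and scipy/lifelines serve as independent oracles in tests.

* **Spearman** ρ is the Pearson correlation of midranks. The two-sided p
  is exact (enumeration of all n! rank permutations) when n ≤ 9 and both
  vectors are tie-free — ties make the permutation null ambiguous, so any
  tie falls back to the approximation — otherwise the t approximation
  t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 df, the dominant convention in the
  statistical software this kind of analysis is run in. |ρ| = 1 under the
  approximation reports the smallest positive float rather than 0.
* **Mann–Whitney U** counts pairs with x > y plus half the ties. The p is
  exact by enumeration of all C(n1+n2, n1) group assignments when
  n1+n2 ≤ 12 and the pooled sample is tie-free; otherwise a normal
  approximation with tie correction and a continuity correction (recorded
  in the method tag).
* **Kaplan–Meier**: product-limit estimator. The median is the smallest
  event time t with S(t) ≤ 0.5 — deterministic on an exact-half plateau.
  Subjects censored at an event time remain in the risk set at that time
  (the standard convention).
* **Log-rank (Mantel–Cox)**, two groups: chi-square on 1 df,
  (Σ(O−E))²/ΣV with the hypergeometric variance per distinct event time;
  when every event falls at a time where one group is absent from the
  risk set, ΣV = 0 and the statistic is defined as 0 (p = 1). At n = 20
  per group the chi-square reference is mildly anti-conservative
  (empirical type-I error ≈ 0.06 at α = 0.05 in the null calibration the
  acceptance script runs), which is a property of the test itself, not of
  this implementation. No multi-group trend test, hazard ratios, or Cox
  regression are in scope.

## Preranked enrichment and subtyping

Per-sample ranked lists order genes by expression descending with a
deterministic alphabetical tie-break. The enrichment score is the classic
weighted Kolmogorov–Smirnov running sum (hits add |metric|^p normalized
to the hit total, default p = 1; misses subtract 1/(N−N_hits); the score
is the running sum at its maximal absolute deviation, so |ES| ≤ 1). The
null is gene-tag permutation — random equal-size gene sets drawn from the
ranked list — which is the standard null for preranked mode;
NES = ES / mean(|null ES| of the same sign), and the empirical p is
one-sided in the observed direction with an add-one correction, flooring
at 1/(n_perm+1). Assignment takes the subtype signature with the highest
NES; exact ties return "ambiguous". Each signature's null stream derives
independently from the call's seed, so results do not depend on signature
order.

Caveats: the ranking metric is the normalized expression value itself
(the workflow this emulates feeds expression directly to the preranked
tool); probe-level "collapse" machinery is replaced by plain symbol
matching because all inputs here are symbol-keyed; and the published
subtype gene sets are external data, so tests and examples use clearly
labeled synthetic subtype signatures (`synthetic_subtype_signatures`).
No FDR across gene-set collections is computed.

## Survival and viability

Survival comparisons administratively censor any record past the horizon
(default 100 days, the monitored window in the design this mirrors)
before estimation. MTT viability uses corrected OD = OD540 − OD650 — the
reference-wavelength subtraction standard for MTT, chosen because the
assay reads both wavelengths without stating a combination formula — and
divides by the mean corrected OD of untreated wells within the same
timepoint stratum. The 50%-viability dose interpolates linearly in
log10(dose) at the first downward crossing; a non-monotonic curve still
yields the first crossing but is flagged.

## Image quantification

The tumor mask binarizes the DAPI channel (Otsu by default, or a fixed
threshold), fills holes, and removes connected components below 50 px
(8-connectivity); area in mm² is area_px · (pixel_size_µm/1000)². The
stained-area ratio applies one fixed marker threshold, shared across all
images of a comparison ("same intensity settings irrespective of
treatment"), inclusively (≥). Nucleus counting removes sub-minimum
components and splits touching nuclei by watershed on the distance
transform, seeded at distance peaks separated by at least the radius of a
minimum-area disk; splitting is on by default and exact on the disk
fixtures the generator produces. A proprietary "pseudocolor" threshold
step is thus replaced by an explicit, reportable threshold. Manual masks
can be supplied by constructing `MaskResult` directly.

## Synthetic data

`simulate_expression` uses a Gaussian copula: a latent standard normal
factor for the gene of interest, planted genes at latent Pearson
r = 2·sin(π·ρ_s/6) — the exact Spearman↔Pearson conversion for the
bivariate normal — and a strictly increasing marginal transform
(lognormal with log-SD 1 by default, mimicking the positivity and skew of
normalized expression), which preserves Spearman correlation exactly in
distribution. The planted genes share the single factor, so their mutual
latent correlation is r²; a design with planted genes mutually
independent is not positive definite once r·sqrt(k) ≥ 1 (e.g. ρ_s = 0.6
on k = 10 genes), whereas the one-factor structure is valid for any k and
leaves the gene-of-interest correlations — the only quantity the ratio
score reads — exactly at the target.

Survival times are exponential per group with administrative censoring at
the horizon. Stain images place an elliptical tumor of the requested area
fraction, stain exactly the requested fraction of tumor pixels (the top
of a smoothed random field, so stains form coherent patches), place
non-overlapping nucleus disks by rejection sampling (raising an error on
infeasible packings), and add Gaussian intensity noise. Subtype panels
up-shift each sample's true-signature genes by `shift_sd` (default 2) in
log space over a lognormal background.

What the generators do **not** emulate: probe effects, batch effects,
inter-gene correlation beyond the planted structure, cell-type mixtures,
irregular tumor boundaries, or uneven illumination. Passing tests
demonstrate correctness of the computations under the stated statistical
model, not robustness to every artifact of real cohorts or microscopes.

## Problem sizes and defaults

The recovery and calibration studies use the sizes the analyses were
designed around: planted-correlation recovery at n = 200 samples with 100
replicates per k ∈ {0, 3, 7, 10}; log-rank null calibration with 2000
simulations of 20 + 20 subjects at hazard 0.05/day censored at 100 days;
subtype recovery on 60 samples (20 per subtype, shift 2 SD, 500
permutations); image recovery on 100 images of 256×256 px spanning
stained fractions 0.05–0.95 at noise SD 0.02. Thresholds default to the
published tier cutoffs; the censoring horizon defaults to 100 days; the
tumor-mask minimum component is 50 px.

## Known limitations

* The exact Spearman p is unavailable in the presence of ties (falls back
  to the t approximation) and is exponential in n (capped at n = 9).
* NES values from gene-tag permutation are not comparable across ranked
  lists of very different lengths or metric scales.
* The log-dose 50%-crossing is an interpolation, not a fitted
  dose–response model (no Hill fitting).
* Watershed splitting assumes roughly convex nuclei; heavily clumped or
  elongated nuclei will be under- or over-split.
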