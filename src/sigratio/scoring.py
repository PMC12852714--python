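"""Correlation-tier classification and signature ratio scoring.

This is the analysis core: each gene of a signature is Spearman-correlated
with a gene of interest, the (rho, p) pair is classified on the published
seven-level tier scale, and the fraction of signature genes reaching any
tier of the requested sign is reported as a ratio score. The denominator
shrinks by one for each signature gene absent from the matrix and by one
when the gene of interest is itself a signature member (self-correlation is
never counted) — generalizing the printed divide-by-8 (two platform-missing
genes) and divide-by-11 (one missing gene, or self-membership) adjustments.

Tier rules, exactly as published: the strongest tier whose conditions hold
wins; r cutoffs are inclusive, p cutoffs strict. Note the deliberate gap:
r in [0.26, 0.30) with p in [0.001, 0.05) classifies as "none" under the
printed rules; ``ClassificationThresholds.relaxed_weak()`` closes it for
sensitivity analyses.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    NEGATIVE_TIERS,
    POSITIVE_TIERS,
    ClassificationThresholds,
    CorrelationResult,
    ExpressionMatrix,
    GeneSignature,
    RatioScore,
    normalize_symbol,
)
from .errors import ComputationError, ValidationError
from .rankstats import spearman
from .signatures import M1, M2

__all__ = [
    "classify_correlation",
    "correlate_signature",
    "ratio_score",
    "score_panel",
    "tier_table",
    "m1_m2_profile",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = ClassificationThresholds()

MIN_SAMPLES = 4


def classify_correlation(
    rho: float, p: float, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Assign the published correlation tier to a (rho, p) pair.

    Returns the strongest tier whose |r| and p conditions both hold, signed
    by rho; "none" when no tier's conditions are met.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError(f"rho out of [-1,1]: {rho}")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p out of [0,1]: {p}")
    mag = abs(rho)
    if mag >= thresholds.strong_r and p < thresholds.strong_p:
        strength = "strong"
    elif mag >= thresholds.moderate_r and p < thresholds.moderate_p:
        strength = "moderate"
    elif mag >= thresholds.weak_r and p < thresholds.weak_p:
        strength = "weak"
    else:
        return "none"
    return f"{strength}_pos" if rho > 0 else f"{strength}_neg"


def correlate_signature(
    expr: ExpressionMatrix,
    gene_of_interest: str,
    signature: GeneSignature,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> list[CorrelationResult]:
    """Classified Spearman correlations between a gene of interest and every
    signature gene present in the matrix (the gene of interest itself is
    skipped when it is a member).

    A signature gene with zero expression variance has no defined
    correlation and classifies as "none"; it still occupies its denominator
    slot.
    """
    goi = normalize_symbol(gene_of_interest)
    if goi not in expr:
        raise ValidationError(f"gene of interest {goi!r} not in matrix")
    if expr.n_samples < MIN_SAMPLES:
        raise ValidationError(
            f"need >= {MIN_SAMPLES} samples, got {expr.n_samples}"
        )
    x = expr.gene(goi)
    results = []
    for g in signature.genes:
        if g == goi or g not in expr:
            continue
        try:
            res = spearman(x, expr.gene(g), gene_a=goi, gene_b=g)
            res = res.with_tier(classify_correlation(res.rho, res.p_two_sided, thresholds))
        except ComputationError:
            res = CorrelationResult(
                gene_a=goi, gene_b=g, rho=0.0, p_two_sided=1.0,
                n=expr.n_samples, tier="none", method="t_approx",
            )
        results.append(res)
    return results


def ratio_score(
    expr: ExpressionMatrix,
    gene_of_interest: str,
    signature: GeneSignature,
    direction: str = "positive",
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> RatioScore:
    """Signature correlation-ratio score for one gene of interest.

    numerator: signature genes whose tier sign matches *direction* (any
    strength). denominator: |signature| - missing genes - self-exclusion.
    """
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction must be 'positive' or 'negative', got {direction!r}")
    goi = normalize_symbol(gene_of_interest)
    if goi not in expr:
        raise ValidationError(f"gene of interest {goi!r} not in matrix")
    self_excluded = goi in signature
    missing = tuple(g for g in signature.genes if g != goi and g not in expr)
    denominator = len(signature) - len(missing) - (1 if self_excluded else 0)
    if denominator <= 0:
        raise ComputationError(
            f"signature {signature.name!r} has no scorable genes in this matrix"
        )
    wanted = POSITIVE_TIERS if direction == "positive" else NEGATIVE_TIERS
    correlations = correlate_signature(expr, goi, signature, thresholds)
    numerator = sum(1 for c in correlations if c.tier in wanted)
    return RatioScore(
        gene_of_interest=goi,
        signature_name=signature.name,
        direction=direction,
        numerator=numerator,
        denominator=denominator,
        ratio=numerator / denominator,
        missing_genes=missing,
        self_excluded=self_excluded,
    )


def _role_direction(signature: GeneSignature) -> str:
    return "negative" if signature.role == "low_risk" else "positive"


def score_panel(
    expr: ExpressionMatrix,
    genes_of_interest: Sequence[str],
    signatures: Sequence[GeneSignature],
    per_subgroup: bool = False,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    directions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Ratio scores for every (gene, signature[, subgroup]) combination.

    The direction defaults from the signature role (low_risk scores the
    negative direction, everything else positive) and can be overridden per
    signature name via *directions*. Subgroups with fewer than four samples
    are flagged ``insufficient_samples`` rather than dropped. Rows are
    ordered lexicographically by (gene, signature, subgroup).
    """
    if per_subgroup and not expr.sample_groups:
        raise ValidationError("per_subgroup scoring needs subgroup labels")
    subgroups = expr.groups() if per_subgroup else [None]
    rows = []
    for goi in sorted(normalize_symbol(g) for g in genes_of_interest):
        for sig in sorted(signatures, key=lambda s: s.name):
            direction = (directions or {}).get(sig.name) or _role_direction(sig)
            for sub in sorted(subgroups, key=lambda s: s or ""):
                sub_expr = expr.subgroup(sub) if sub is not None else expr
                base = {
                    "gene": goi,
                    "signature": sig.name,
                    "subgroup": sub if sub is not None else "all",
                    "direction": direction,
                }
                if sub_expr.n_samples < MIN_SAMPLES:
                    rows.append(
                        {**base, "numerator": np.nan, "denominator": np.nan,
                         "ratio": np.nan, "missing_genes": "", "self_excluded": False,
                         "flag": "insufficient_samples"}
                    )
                    continue
                score = ratio_score(sub_expr, goi, sig, direction, thresholds)
                rows.append(
                    {**base, "numerator": score.numerator,
                     "denominator": score.denominator, "ratio": score.ratio,
                     "missing_genes": ";".join(score.missing_genes),
                     "self_excluded": score.self_excluded, "flag": ""}
                )
    return pd.DataFrame(rows)


def tier_table(
    expr: ExpressionMatrix,
    gene_of_interest: str,
    marker_genes: Sequence[str],
    per_subgroup: bool = False,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Subgroup x marker matrix of correlation tiers for one gene of interest.

    Markers absent from the matrix get the cell value "absent"; the gene of
    interest paired with itself gets "self". Suitable for heat-map export.
    """
    if per_subgroup and not expr.sample_groups:
        raise ValidationError("per_subgroup table needs subgroup labels")
    goi = normalize_symbol(gene_of_interest)
    markers = [normalize_symbol(m) for m in marker_genes]
    subgroups = expr.groups() if per_subgroup else ["all"]
    table = {}
    for sub in subgroups:
        sub_expr = expr.subgroup(sub) if per_subgroup else expr
        row = {}
        for m in markers:
            if m == goi:
                row[m] = "self"
            elif m not in sub_expr:
                row[m] = "absent"
            elif sub_expr.n_samples < MIN_SAMPLES:
                row[m] = "not_computable"
            else:
                try:
                    res = spearman(sub_expr.gene(goi), sub_expr.gene(m), goi, m)
                    row[m] = classify_correlation(res.rho, res.p_two_sided, thresholds)
                except ComputationError:
                    row[m] = "none"
        table[sub] = row
    return pd.DataFrame.from_dict(table, orient="index", columns=markers)


def m1_m2_profile(
    expr: ExpressionMatrix,
    gene_of_interest: str,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> tuple[RatioScore, RatioScore]:
    """Positive-direction ratio scores of a gene of interest against the M1
    and M2 macrophage profiles, with the self/missing denominator rules
    (e.g. TREM2 against M2 divides by 11)."""
    return (
        ratio_score(expr, gene_of_interest, M1, "positive", thresholds),
        ratio_score(expr, gene_of_interest, M2, "positive", thresholds),
    )
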