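"""Survival comparison and MTT viability normalization.

Mirrors the in vivo / in vitro analysis arms: Kaplan-Meier curves with a
log-rank (Mantel-Cox) comparison under administrative censoring at a fixed
horizon (100 days by default), and normalization of MTT optical densities
(540 nm signal minus 650 nm reference, scaled to the untreated mean per
timepoint) with a log-dose interpolated 50%-viability crossing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import KMCurve, SurvivalRecord, TestResult, ViabilityRecord
from .errors import ComputationError, ValidationError
from .rankstats import km_estimate, logrank_test

__all__ = [
    "censor_at_horizon",
    "compare_survival",
    "SurvivalComparison",
    "normalize_viability",
    "summarize_viability",
    "dose_at_fraction",
    "DoseEstimate",
    "DEFAULT_HORIZON_DAYS",
]

DEFAULT_HORIZON_DAYS = 100.0


@dataclass(frozen=True)
class SurvivalComparison:
    test: TestResult
    curves: Mapping[str, KMCurve]

    @property
    def medians(self) -> dict[str, float | None]:
        return {g: c.median for g, c in self.curves.items()}


def censor_at_horizon(
    records: Sequence[SurvivalRecord], horizon_days: float = DEFAULT_HORIZON_DAYS
) -> list[SurvivalRecord]:
    """Administratively censor any record observed past the horizon."""
    if not (np.isfinite(horizon_days) and horizon_days > 0):
        raise ValidationError("censor horizon must be > 0")
    out = []
    for r in records:
        if r.time_days > horizon_days:
            out.append(SurvivalRecord(r.subject_id, horizon_days, False, r.group))
        else:
            out.append(r)
    return out


def compare_survival(
    records: Sequence[SurvivalRecord],
    group_a: str,
    group_b: str,
    censor_horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> SurvivalComparison:
    """Log-rank comparison of two groups with per-group KM curves.

    Subjects alive (or with any outcome recorded) past the horizon are
    censored at the horizon before estimation.
    """
    selected = [r for r in records if r.group in (group_a, group_b)]
    for g in (group_a, group_b):
        if not any(r.group == g for r in selected):
            raise ValidationError(f"group {g!r} has no records")
    selected = censor_at_horizon(selected, censor_horizon_days)
    test = logrank_test(selected)
    curves = {
        g: km_estimate([r for r in selected if r.group == g]) for g in (group_a, group_b)
    }
    return SurvivalComparison(test=test, curves=curves)


def normalize_viability(
    records: Sequence[ViabilityRecord], untreated_label: str | None = None
) -> list[ViabilityRecord]:
    """Fill viability_fraction from background-corrected ODs.

    Corrected OD = od_540 - od_650. Within each timepoint stratum, the
    fraction is the corrected OD divided by the mean corrected OD of the
    untreated records (dose 0, or *untreated_label* when given).
    """
    if not records:
        raise ValidationError("no viability records")

    def is_untreated(r: ViabilityRecord) -> bool:
        if untreated_label is not None:
            return r.treatment_label == untreated_label
        return r.dose_uM == 0.0

    out = []
    for tp in sorted({r.timepoint_h for r in records}):
        stratum = [r for r in records if r.timepoint_h == tp]
        baseline_ods = [r.corrected_od for r in stratum if is_untreated(r)]
        if not baseline_ods:
            raise ValidationError(f"timepoint {tp} h has no untreated records")
        baseline = float(np.mean(baseline_ods))
        if baseline <= 0:
            raise ComputationError(
                f"untreated mean corrected OD is non-positive at {tp} h"
            )
        for r in stratum:
            out.append(
                ViabilityRecord(
                    treatment_label=r.treatment_label,
                    dose_uM=r.dose_uM,
                    timepoint_h=r.timepoint_h,
                    od_540=r.od_540,
                    od_650=r.od_650,
                    viability_fraction=r.corrected_od / baseline,
                )
            )
    return out


def summarize_viability(records: Sequence[ViabilityRecord]) -> pd.DataFrame:
    """Mean and SD of viability_fraction per (timepoint, dose), replicate
    wells pooled."""
    rows = [
        {
            "timepoint_h": r.timepoint_h,
            "dose_uM": r.dose_uM,
            "viability_fraction": r.viability_fraction,
        }
        for r in records
        if r.viability_fraction is not None
    ]
    if not rows:
        raise ValidationError("records have no viability_fraction (normalize first)")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["timepoint_h", "dose_uM"])["viability_fraction"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )


@dataclass(frozen=True)
class DoseEstimate:
    """Interpolated dose at a target viability fraction."""

    dose: float | None
    crossed: bool
    monotonic: bool


def dose_at_fraction(
    doses: Sequence[float],
    fractions: Sequence[float],
    fraction: float = 0.5,
) -> DoseEstimate:
    """Dose at the first downward crossing of a viability fraction.

    Interpolates linearly in log10(dose) between the bracketing points; the
    dose is None when the curve never reaches the target. A non-monotonic
    curve still yields the first crossing, flagged via ``monotonic=False``.
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if d.ndim != 1 or d.shape != f.shape or d.size < 1:
        raise ValidationError("doses and fractions must be equal-length 1-D arrays")
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValidationError("doses must be positive and strictly increasing")
    if np.any(f < 0) or np.any(f > 1):
        raise ValidationError("fractions must lie in [0,1]")
    monotonic = bool(np.all(np.diff(f) <= 0))
    if f[0] <= fraction:
        return DoseEstimate(dose=float(d[0]), crossed=True, monotonic=monotonic)
    for i in range(1, d.size):
        if f[i] <= fraction:
            t = (f[i - 1] - fraction) / (f[i - 1] - f[i])
            logd = math.log10(d[i - 1]) + t * (math.log10(d[i]) - math.log10(d[i - 1]))
            return DoseEstimate(dose=float(10**logd), crossed=True, monotonic=monotonic)
    return DoseEstimate(dose=None, crossed=False, monotonic=monotonic)
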