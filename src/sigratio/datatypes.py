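"""Core domain types shared by every analysis stage.

Gene symbols are matched case-insensitively: every constructor upper-cases
symbols and strips hyphens, so the platform spellings ``SIGLEC-10`` and
``SIGLEC10`` collapse to one key. No alias expansion is performed beyond
that — a symbol unknown to a dataset simply counts as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ComputationError, ValidationError

__all__ = [
    "normalize_symbol",
    "ExpressionMatrix",
    "GeneSignature",
    "ClassificationThresholds",
    "CorrelationResult",
    "RatioScore",
    "SurvivalRecord",
    "StainImage",
    "SubtypeCall",
    "ViabilityRecord",
    "TestResult",
    "KMCurve",
    "MaskResult",
    "RankedList",
    "TIERS",
    "POSITIVE_TIERS",
    "NEGATIVE_TIERS",
    "SIGNATURE_ROLES",
]

#: The seven-level correlation tier scale.
TIERS = (
    "strong_pos",
    "moderate_pos",
    "weak_pos",
    "none",
    "weak_neg",
    "moderate_neg",
    "strong_neg",
)
POSITIVE_TIERS = frozenset({"weak_pos", "moderate_pos", "strong_pos"})
NEGATIVE_TIERS = frozenset({"weak_neg", "moderate_neg", "strong_neg"})

SIGNATURE_ROLES = ("high_risk", "low_risk", "M1", "M2", "subtype", "marker")


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: upper-case, hyphens stripped."""
    s = str(symbol).strip().upper().replace("-", "")
    if not s:
        raise ValidationError("empty gene symbol")
    return s


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, with optional subgroup labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [normalize_symbol(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.sample_groups is not None:
            self.sample_groups = {str(k): str(v) for k, v in self.sample_groups.items()}
            unknown = set(self.sample_groups) - set(self.sample_ids)
            if unknown:
                raise ValidationError(f"group labels for unknown samples: {sorted(unknown)}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._gene_index

    def gene(self, symbol: str) -> np.ndarray:
        """Expression vector (over samples) for one gene."""
        key = normalize_symbol(symbol)
        try:
            return self.values[self._gene_index[key]]
        except KeyError:
            raise ValidationError(f"gene {key!r} not in matrix") from None

    def groups(self) -> list[str]:
        """Sorted distinct subgroup labels (empty if unlabeled)."""
        if not self.sample_groups:
            return []
        return sorted(set(self.sample_groups.values()))

    def subgroup(self, label: str) -> "ExpressionMatrix":
        """Column subset restricted to one subgroup label."""
        if not self.sample_groups:
            raise ValidationError("matrix has no subgroup labels")
        cols = [i for i, s in enumerate(self.sample_ids) if self.sample_groups.get(s) == label]
        if not cols:
            raise ValidationError(f"no samples in subgroup {label!r}")
        sids = [self.sample_ids[i] for i in cols]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=sids,
            values=self.values[:, cols],
            sample_groups={s: self.sample_groups[s] for s in sids if s in self.sample_groups},
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class GeneSignature:
    """Named, ordered gene list with a functional role."""

    name: str
    genes: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        genes = tuple(normalize_symbol(g) for g in self.genes)
        if not genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        if len(set(genes)) != len(genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        if self.role not in SIGNATURE_ROLES:
            raise ValidationError(f"unknown signature role {self.role!r}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


@dataclass(frozen=True)
class ClassificationThresholds:
    """Correlation-tier cutoffs.

    r thresholds are inclusive (>= for positive, <= negative mirror), p
    thresholds strict (<). Defaults are the published three-tier scale:
    weak |r| >= 0.26 with p < 0.001, moderate |r| >= 0.30 with p < 0.05,
    strong |r| >= 0.50 with p < 0.05.
    """

    weak_r: float = 0.26
    weak_p: float = 0.001
    moderate_r: float = 0.30
    moderate_p: float = 0.05
    strong_r: float = 0.50
    strong_p: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.weak_r < self.moderate_r < self.strong_r < 1):
            raise ValidationError("require 0 < weak_r < moderate_r < strong_r < 1")
        if not (0 < self.weak_p <= self.moderate_p <= 1):
            raise ValidationError("require 0 < weak_p <= moderate_p <= 1")
        if not (0 < self.strong_p <= 1):
            raise ValidationError("require 0 < strong_p <= 1")

    def relaxed_weak(self) -> "ClassificationThresholds":
        """Sensitivity variant with the weak tier's p cutoff relaxed to the
        moderate tier's (closes the r in [weak_r, moderate_r) gap)."""
        return ClassificationThresholds(
            weak_r=self.weak_r,
            weak_p=self.moderate_p,
            moderate_r=self.moderate_r,
            moderate_p=self.moderate_p,
            strong_r=self.strong_r,
            strong_p=self.strong_p,
        )


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho and two-sided p for one gene pair, with optional tier."""

    gene_a: str
    gene_b: str
    rho: float
    p_two_sided: float
    n: int
    tier: str | None = None
    method: str = "t_approx"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"rho out of [-1,1]: {self.rho}")
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValidationError(f"p out of [0,1]: {self.p_two_sided}")
        if self.tier is not None and self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")

    def with_tier(self, tier: str) -> "CorrelationResult":
        return CorrelationResult(
            self.gene_a, self.gene_b, self.rho, self.p_two_sided, self.n, tier, self.method
        )


@dataclass(frozen=True)
class RatioScore:
    """Fraction of a signature correlated (in the requested direction) with a
    gene of interest, with the denominator-adjustment bookkeeping."""

    gene_of_interest: str
    signature_name: str
    direction: str
    numerator: int
    denominator: int
    ratio: float
    missing_genes: tuple[str, ...] = ()
    self_excluded: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValidationError(f"direction must be positive/negative, got {self.direction!r}")
        if self.denominator <= 0:
            raise ValidationError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValidationError("numerator must lie in [0, denominator]")
        if abs(self.ratio - self.numerator / self.denominator) > 1e-12:
            raise ValidationError("ratio != numerator/denominator")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time_days: float
    event: bool
    group: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_days) or self.time_days <= 0:
            raise ValidationError(f"time_days must be > 0, got {self.time_days}")


@dataclass
class StainImage:
    """Two-channel fluorescence raster: marker + nuclear (DAPI)."""

    marker: np.ndarray | None
    nuclear: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        if self.nuclear.ndim != 2 or self.nuclear.size == 0:
            raise ValidationError("nuclear channel must be a non-empty 2-D raster")
        if not np.all(np.isfinite(self.nuclear)) or np.any(self.nuclear < 0):
            raise ValidationError("nuclear intensities must be finite and non-negative")
        if self.marker is not None:
            self.marker = np.asarray(self.marker, dtype=float)
            if self.marker.shape != self.nuclear.shape:
                raise ValidationError("marker and nuclear channels must share a shape")
            if not np.all(np.isfinite(self.marker)) or np.any(self.marker < 0):
                raise ValidationError("marker intensities must be finite and non-negative")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ValidationError("pixel_size_um must be > 0")

    @property
    def has_marker(self) -> bool:
        return self.marker is not None


@dataclass(frozen=True)
class SubtypeCall:
    """Per-sample enrichment-based subtype assignment (argmax NES)."""

    sample_id: str
    nes_by_signature: Mapping[str, float]
    assigned: str


@dataclass
class ViabilityRecord:
    """One well of an MTT readout (540 nm signal, 650 nm reference)."""

    treatment_label: str
    dose_uM: float
    timepoint_h: int
    od_540: float
    od_650: float
    viability_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.dose_uM < 0:
            raise ValidationError("dose_uM must be >= 0")
        if not (np.isfinite(self.od_540) and np.isfinite(self.od_650)):
            raise ValidationError("OD readings must be finite")

    @property
    def corrected_od(self) -> float:
        return self.od_540 - self.od_650


@dataclass(frozen=True)
class TestResult:
    """Generic two-sample test outcome with the method tag recorded."""

    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValidationError(f"p out of [0,1]: {self.p_two_sided}")
        if self.method not in ("exact", "normal_approx", "t_approx", "chi_square"):
            raise ValidationError(f"unknown method tag {self.method!r}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over one group."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median: float | None

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if s.size and (np.any(np.diff(s) > 1e-12) or np.any(s < -1e-12) or np.any(s > 1 + 1e-12)):
            raise ValidationError("survival must be a non-increasing step function in [0,1]")

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass
class MaskResult:
    """Binary segmentation with pixel and physical areas."""

    mask: np.ndarray
    area_px: int
    area_mm2: float
    threshold_used: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if int(self.mask.sum()) != self.area_px:
            raise ValidationError("area_px inconsistent with mask")


@dataclass
class RankedList:
    """Genes ordered by decreasing ranking metric (ties broken by symbol)."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [normalize_symbol(g) for g in self.gene_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("ranked list has duplicate genes")
        self.metric = np.asarray(self.metric, dtype=float)
        if self.metric.shape != (len(self.gene_ids),):
            raise ValidationError("metric length must match gene list")
        if not np.all(np.isfinite(self.metric)):
            raise ValidationError("ranking metric must be finite")
        order = np.lexsort((np.array(self.gene_ids), -self.metric))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValidationError("list must be sorted by decreasing metric, symbol-ascending ties")

    def __len__(self) -> int:
        return len(self.gene_ids)
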