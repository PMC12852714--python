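"""Synthetic-data generators with known ground truth.

Every downstream stage is exercised on data these generators produce:

* expression matrices with a planted Spearman correlation between a gene
  of interest and a chosen subset of signature genes, via a one-factor
  Gaussian copula (latent Pearson r = 2 sin(pi rho_s / 6), the exact
  Spearman-to-Pearson conversion for the bivariate normal copula; the
  planted genes share the gene-of-interest factor, so their mutual latent
  correlation is r^2 — the only factor structure that stays positive
  definite for arbitrarily many planted genes);
* exponential survival times with group-specific hazards and
  administrative censoring at a horizon;
* two-channel stain images with exact ground-truth tumor mask, stained
  fraction, and nucleus count;
* subtype panels where each sample's true-signature genes are up-shifted
  over a lognormal background.

All generators are pure functions of their seed: identical arguments and
seed reproduce identical output arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datatypes import ExpressionMatrix, GeneSignature, StainImage, SurvivalRecord
from .errors import ComputationError, ValidationError

__all__ = [
    "ExpressionSimSpec",
    "ExpressionTruth",
    "simulate_expression",
    "simulate_survival",
    "StainTruth",
    "simulate_stain_image",
    "simulate_subtype_samples",
    "synthetic_subtype_signatures",
    "spearman_to_latent_pearson",
]


def spearman_to_latent_pearson(rho_s: float) -> float:
    """Latent Pearson correlation reproducing a target Spearman rho under a
    Gaussian copula: r = 2 sin(pi rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class ExpressionSimSpec:
    """Design of one synthetic expression matrix.

    n_samples may be an int (single unlabeled subgroup) or a mapping of
    subgroup label to size. The planted correlation applies within every
    subgroup independently.
    """

    gene_of_interest: str
    signature: GeneSignature
    n_samples: int | Mapping[str, int] = 200
    planted_rho: float = 0.6
    n_planted: int | None = None
    background_genes: int = 20
    marginal: str = "lognormal"
    missing_genes: Sequence[str] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.planted_rho < 1.0:
            raise ValidationError("planted_rho must lie in (-1, 1)")
        if self.n_planted is None:
            self.n_planted = len(self.signature)
        if not 0 <= self.n_planted <= len(self.signature):
            raise ValidationError("n_planted must lie in [0, |signature|]")
        if self.marginal not in ("lognormal", "normal"):
            raise ValidationError("marginal must be 'lognormal' or 'normal'")
        if self.background_genes < 0:
            raise ValidationError("background_genes must be >= 0")


@dataclass(frozen=True)
class ExpressionTruth:
    """Ground truth accompanying a simulated matrix."""

    gene_of_interest: str
    planted_genes: tuple[str, ...]
    target_rho: float
    latent_r: float
    missing_genes: tuple[str, ...]


def _marginal_transform(z: np.ndarray, kind: str) -> np.ndarray:
    # strictly increasing, hence Spearman-preserving; log-SD 1 lognormal
    return np.exp(z) if kind == "lognormal" else z


def simulate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Sample an expression matrix with planted rank correlation.

    The first ``n_planted`` signature genes share a latent factor with the
    gene of interest at latent correlation r = 2 sin(pi rho/6); remaining
    signature and background genes are independent. The marginal transform
    is strictly increasing, so the planted Spearman correlation survives
    it exactly in distribution. Genes listed in ``missing_genes`` are
    dropped from the output (emulating platform-missing genes).
    """
    rng = np.random.default_rng(spec.seed)
    goi = spec.gene_of_interest
    sig_genes = list(spec.signature.genes)
    if goi in sig_genes:
        sig_genes.remove(goi)
    planted = tuple(sig_genes[: spec.n_planted])
    unplanted = sig_genes[spec.n_planted :]
    background = [f"BG{i:04d}" for i in range(spec.background_genes)]
    gene_ids = [goi, *sig_genes, *background]
    r = spearman_to_latent_pearson(spec.planted_rho)
    if abs(r) >= 1.0:
        raise ComputationError("implied latent correlation is not positive definite")

    if isinstance(spec.n_samples, Mapping):
        blocks = dict(spec.n_samples)
    else:
        blocks = {None: int(spec.n_samples)}
    cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for label, n in blocks.items():
        if n < 1:
            raise ValidationError("each subgroup needs >= 1 sample")
        z0 = rng.standard_normal(n)
        rows = [z0]
        for g in planted:
            eps = rng.standard_normal(n)
            rows.append(r * z0 + math.sqrt(1.0 - r * r) * eps)
        for _ in [*unplanted, *background]:
            rows.append(rng.standard_normal(n))
        block = np.vstack(rows)
        cols.append(block)
        prefix = label if label is not None else "S"
        ids = [f"{prefix}_{i:04d}" for i in range(n)]
        sample_ids.extend(ids)
        if label is not None:
            groups.update({s: label for s in ids})
    values = _marginal_transform(np.hstack(cols), spec.marginal)

    missing = tuple(g for g in spec.missing_genes)
    from .datatypes import normalize_symbol

    missing_norm = {normalize_symbol(g) for g in missing}
    keep = [i for i, g in enumerate(gene_ids) if normalize_symbol(g) not in missing_norm]
    expr = ExpressionMatrix(
        gene_ids=[gene_ids[i] for i in keep],
        sample_ids=sample_ids,
        values=values[keep],
        sample_groups=groups or None,
    )
    truth = ExpressionTruth(
        gene_of_interest=goi,
        planted_genes=planted,
        target_rho=spec.planted_rho,
        latent_r=r,
        missing_genes=missing,
    )
    return expr, truth


def simulate_survival(
    n_per_group: Mapping[str, int],
    hazard_per_group: Mapping[str, float],
    censor_horizon_days: float = 100.0,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Exponential survival times with administrative censoring.

    Event times are drawn per group from Exp(hazard) (hazard in 1/day);
    times past the horizon are recorded as censored at the horizon.
    """
    if not (np.isfinite(censor_horizon_days) and censor_horizon_days > 0):
        raise ValidationError("censor horizon must be > 0")
    if set(n_per_group) != set(hazard_per_group):
        raise ValidationError("n_per_group and hazard_per_group must share keys")
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(n_per_group):
        n = int(n_per_group[group])
        hazard = float(hazard_per_group[group])
        if hazard <= 0:
            raise ValidationError("hazards must be > 0")
        times = rng.exponential(scale=1.0 / hazard, size=n)
        for i, t in enumerate(times):
            event = t <= censor_horizon_days
            records.append(
                SurvivalRecord(
                    subject_id=f"{group}_{i:03d}",
                    time_days=float(t) if event else censor_horizon_days,
                    event=bool(event),
                    group=group,
                )
            )
    return records


@dataclass(frozen=True)
class StainTruth:
    """Exact masks and counts behind a simulated stain image."""

    tumor_mask: np.ndarray
    stained_mask: np.ndarray
    nucleus_centers: tuple[tuple[int, int], ...]
    tumor_fraction: float
    stained_fraction: float
    n_nuclei: int


def _elliptical_tumor(shape: tuple[int, int], fraction: float, rng) -> np.ndarray:
    h, w = shape
    target = fraction * h * w
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    if fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    ratio = rng.uniform(0.6, 1.0)  # minor/major axis ratio
    # area = pi a b = pi a^2 ratio
    a = math.sqrt(target / (math.pi * ratio))
    b = a * ratio
    theta = rng.uniform(0, math.pi)
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _smooth_field(shape: tuple[int, int], rng, sigma: float = 8.0) -> np.ndarray:
    from scipy import ndimage as ndi

    return ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def simulate_stain_image(
    shape: tuple[int, int] = (256, 256),
    tumor_fraction: float = 0.3,
    stained_fraction_within_tumor: float = 0.25,
    n_nuclei: int = 50,
    noise_sd: float = 0.02,
    pixel_size_um: float = 1.0,
    seed: int = 0,
    nucleus_radius_px: int = 5,
    min_separation_px: int | None = None,
) -> tuple[StainImage, StainTruth]:
    """Two-channel synthetic stain image with exact ground truth.

    The tumor is a randomly oriented ellipse of approximately
    ``tumor_fraction`` of the frame; the marker channel stains exactly
    ``stained_fraction_within_tumor`` of the tumor pixels (chosen as the
    top fraction of a smoothed random field, so the stain forms coherent
    patches); nuclei are disks placed inside the tumor with enforced
    center separation. Gaussian intensity noise is added to both channels.

    Intensity design (before noise): background 0.05, diffuse tumor DAPI
    0.40, nucleus disks 1.0 on the nuclear channel; marker 0.05 outside
    the stained region and 0.85 inside.
    """
    if not (0.0 <= tumor_fraction <= 1.0 and 0.0 <= stained_fraction_within_tumor <= 1.0):
        raise ValidationError("fractions must lie in [0,1]")
    if noise_sd < 0 or n_nuclei < 0:
        raise ValidationError("noise_sd and n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    tumor = _elliptical_tumor(shape, tumor_fraction, rng)
    tumor_px = int(tumor.sum())

    # stained region: top `stained_fraction` of a smooth field inside the tumor
    stained = np.zeros(shape, dtype=bool)
    n_stained = int(round(stained_fraction_within_tumor * tumor_px))
    if n_stained > 0 and tumor_px > 0:
        fld = _smooth_field(shape, rng)
        vals = fld[tumor]
        cutoff_idx = np.argsort(vals)[::-1][:n_stained]
        ti, tj = np.nonzero(tumor)
        stained[ti[cutoff_idx], tj[cutoff_idx]] = True

    # nuclei: rejection-sample centers inside the tumor with separation
    if min_separation_px is None:
        min_separation_px = 2 * nucleus_radius_px + 3
    centers: list[tuple[int, int]] = []
    if n_nuclei > 0:
        if tumor_px == 0:
            raise ComputationError("cannot place nuclei: tumor region is empty")
        ti, tj = np.nonzero(tumor)
        interior = (
            (ti >= nucleus_radius_px)
            & (ti < shape[0] - nucleus_radius_px)
            & (tj >= nucleus_radius_px)
            & (tj < shape[1] - nucleus_radius_px)
        )
        ti, tj = ti[interior], tj[interior]
        if ti.size == 0:
            raise ComputationError("cannot place nuclei: no interior tumor pixels")
        attempts = 0
        max_attempts = 200 * n_nuclei
        while len(centers) < n_nuclei:
            if attempts >= max_attempts:
                raise ComputationError(
                    f"infeasible packing: placed {len(centers)} of {n_nuclei} nuclei"
                )
            k = rng.integers(ti.size)
            cy, cx = int(ti[k]), int(tj[k])
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 >= min_separation_px**2 for y, x in centers
            ):
                centers.append((cy, cx))
            attempts += 1

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    nuclei_mask = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        nuclei_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius_px**2

    nuclear = np.full(shape, 0.05)
    nuclear[tumor] = 0.40
    nuclear[nuclei_mask] = 1.0
    marker = np.full(shape, 0.05)
    marker[stained] = 0.85
    if noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, noise_sd, shape)
        marker = marker + rng.normal(0.0, noise_sd, shape)
    nuclear = np.clip(nuclear, 0.0, None)
    marker = np.clip(marker, 0.0, None)

    image = StainImage(marker=marker, nuclear=nuclear, pixel_size_um=pixel_size_um)
    truth = StainTruth(
        tumor_mask=tumor,
        stained_mask=stained,
        nucleus_centers=tuple(centers),
        tumor_fraction=tumor_px / (shape[0] * shape[1]),
        stained_fraction=(n_stained / tumor_px) if tumor_px else 0.0,
        n_nuclei=len(centers),
    )
    return image, truth


def synthetic_subtype_signatures(
    names: Sequence[str] = ("Classical", "Proneural", "Mesenchymal"),
    genes_per_signature: int = 50,
) -> list[GeneSignature]:
    """Disjoint synthetic subtype gene sets (stand-ins for published subtype
    signatures, which are external data); gene symbols are prefixed with the
    subtype name so their synthetic origin is explicit."""
    sigs = []
    for name in names:
        genes = tuple(f"{name.upper()}{i:03d}" for i in range(genes_per_signature))
        sigs.append(GeneSignature(name=name, genes=genes, role="subtype"))
    return sigs


def simulate_subtype_samples(
    n_per_subtype: int = 20,
    shift_sd: float = 2.0,
    background_genes: int = 1000,
    signatures: Sequence[GeneSignature] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expression panel where each sample up-shifts its true subtype's
    signature genes by ``shift_sd`` standard deviations (in log space) over
    a lognormal background. Returns the matrix and sample -> true subtype.
    """
    if shift_sd < 0:
        raise ValidationError("shift_sd must be >= 0")
    if signatures is None:
        signatures = synthetic_subtype_signatures()
    rng = np.random.default_rng(seed)
    sig_genes = [g for s in signatures for g in s.genes]
    if len(set(sig_genes)) != len(sig_genes):
        raise ValidationError("subtype signatures must be disjoint")
    gene_ids = sig_genes + [f"BG{i:04d}" for i in range(background_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sample_ids, truth = [], {}
    cols = []
    for sig in signatures:
        for i in range(int(n_per_subtype)):
            sid = f"{sig.name}_{i:03d}"
            z = rng.standard_normal(len(gene_ids))
            for g in sig.genes:
                z[gene_index[g]] += shift_sd
            cols.append(np.exp(z))
            sample_ids.append(sid)
            truth[sid] = sig.name
    expr = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.column_stack(cols),
        sample_groups=dict(truth),
    )
    return expr, truth
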