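"""Fluorescence stain quantification.

Reproduces the computerized image-analysis arm: a DAPI-derived tumor mask
with area in mm^2, the ratio of marker-stained area to tumor area under a
fixed intensity threshold shared across a comparison, nucleus counting
with distance-transform watershed splitting, stained-area-per-nucleus for
cultured cells, and pairwise Mann-Whitney group comparisons of per-image
values. Segmentation primitives come from scikit-image/scipy.ndimage;
thresholds are inclusive (>=), components use 8-connectivity, and pixel
coordinates are row-major with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .datatypes import MaskResult, TestResult
from .errors import ComputationError, ValidationError
from .rankstats import mann_whitney_u

__all__ = [
    "tumor_mask",
    "stained_area_ratio",
    "count_nuclei",
    "stain_per_nucleus",
    "StainPerNucleus",
    "compare_groups",
    "area_px_to_mm2",
]

DEFAULT_MIN_COMPONENT_PX = 50


def area_px_to_mm2(area_px: int, pixel_size_um: float) -> float:
    return area_px * (pixel_size_um / 1000.0) ** 2


def _as_raster(img: np.ndarray, name: str) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError(f"{name} must be a non-empty 2-D raster")
    if not np.all(np.isfinite(img)):
        raise ValidationError(f"{name} must be finite")
    return img


def _threshold(img: np.ndarray, method: str, fixed_threshold: float | None) -> float:
    if method == "fixed":
        if fixed_threshold is None:
            raise ValidationError("fixed threshold method requires fixed_threshold")
        return float(fixed_threshold)
    if method != "otsu":
        raise ValidationError(f"unknown threshold method {method!r}")
    if np.ptp(img) == 0:
        raise ComputationError("cannot compute Otsu threshold on a constant image")
    return float(threshold_otsu(img))


def tumor_mask(
    nuclear: np.ndarray,
    pixel_size_um: float,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
) -> MaskResult:
    """Segment the DAPI-positive tumor region.

    Binarize (Otsu by default), fill holes, drop connected components
    smaller than *min_component_px*; the surviving components form the
    tumor mask, whose area is reported in pixels and mm^2.
    """
    nuclear = _as_raster(nuclear, "nuclear")
    if not (np.isfinite(pixel_size_um) and pixel_size_um > 0):
        raise ValidationError("pixel_size_um must be > 0")
    if np.all(nuclear == 0):
        raise ComputationError("all-zero nuclear image: empty tumor mask")
    thr = _threshold(nuclear, method, fixed_threshold)
    bw = nuclear >= thr
    bw = ndi.binary_fill_holes(bw)
    # drop components with fewer than min_component_px pixels
    bw = remove_small_objects(bw, max_size=int(min_component_px) - 1, connectivity=2)
    area_px = int(bw.sum())
    if area_px == 0:
        raise ComputationError("empty tumor mask after thresholding")
    return MaskResult(
        mask=bw,
        area_px=area_px,
        area_mm2=area_px_to_mm2(area_px, pixel_size_um),
        threshold_used=thr,
    )


def stained_area_ratio(
    marker: np.ndarray, tumor: MaskResult, threshold: float
) -> float:
    """Fraction of the tumor mask whose marker intensity reaches *threshold*.

    The threshold is a fixed configuration value shared across every image
    of a comparison (same intensity settings irrespective of treatment).
    """
    marker = _as_raster(marker, "marker")
    if marker.shape != tumor.mask.shape:
        raise ValidationError("marker and tumor mask shapes differ")
    if tumor.area_px == 0:
        raise ComputationError("empty tumor mask")
    stained = int(np.sum((marker >= threshold) & tumor.mask))
    return stained / tumor.area_px


def count_nuclei(
    nuclear: np.ndarray,
    min_area_px: int = 30,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    split_touching: bool = True,
    min_peak_distance: int | None = None,
) -> int:
    """Count DAPI-stained nuclei.

    Binarize, label 8-connected components, drop components below
    *min_area_px*, and (by default) split touching nuclei by watershed on
    the distance transform, seeded at distance-transform peaks at least
    *min_peak_distance* apart (default: the radius of a disk of
    *min_area_px*). Zero is a valid count.
    """
    nuclear = _as_raster(nuclear, "nuclear")
    if np.ptp(nuclear) == 0:
        return 0
    thr = _threshold(nuclear, method, fixed_threshold)
    bw = nuclear >= thr
    bw = remove_small_objects(bw, max_size=int(min_area_px) - 1, connectivity=2)
    if not bw.any():
        return 0
    lbl = label(bw, connectivity=2)
    if not split_touching:
        return int(lbl.max())
    if min_peak_distance is None:
        min_peak_distance = max(3, int(round(np.sqrt(min_area_px / np.pi))))
    distance = ndi.distance_transform_edt(bw)
    coords = peak_local_max(
        distance, min_distance=int(min_peak_distance), labels=lbl, exclude_border=False
    )
    if coords.shape[0] == 0:
        return int(lbl.max())
    markers = np.zeros_like(lbl)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    segmented = watershed(-distance, markers, mask=bw)
    return int(np.sum(np.unique(segmented) > 0))


@dataclass(frozen=True)
class StainPerNucleus:
    """Marker-positive pixels per detected nucleus; value is None (undefined)
    when no nucleus is found."""

    value: float | None
    stained_px: int
    n_nuclei: int


def stain_per_nucleus(
    marker: np.ndarray,
    nuclear: np.ndarray,
    marker_threshold: float,
    **count_kwargs,
) -> StainPerNucleus:
    """Marker-positive pixel count over the whole image divided by the
    number of nuclei (cultured-cell readout)."""
    marker = _as_raster(marker, "marker")
    nuclear = _as_raster(nuclear, "nuclear")
    if marker.shape != nuclear.shape:
        raise ValidationError("marker and nuclear shapes differ")
    stained = int(np.sum(marker >= marker_threshold))
    n = count_nuclei(nuclear, **count_kwargs)
    value = stained / n if n > 0 else None
    return StainPerNucleus(value=value, stained_px=stained, n_nuclei=n)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]]
) -> dict[tuple[str, str], TestResult]:
    """Pairwise Mann-Whitney U tests over per-image values by group.

    Each image-section value is one observation (the published design used
    3 sections x 7 animals per group).
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValidationError("compare_groups needs at least two groups")
    for g in groups:
        if len(values_by_group[g]) == 0:
            raise ValidationError(f"group {g!r} has no values")
    return {
        (a, b): mann_whitney_u(values_by_group[a], values_by_group[b])
        for a, b in combinations(groups, 2)
    }
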