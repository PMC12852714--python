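"""Readers and writers for the tabular and image formats the pipeline uses.

Expression tables follow the GlioVis-style export layout: first column holds
gene symbols, the header row holds sample ids, and the delimiter (comma or
tab) is sniffed. Survival tables are CSV with subject_id/time_days/event/
group columns. Images are TIFF or PNG with one (nuclear) or two
(marker + nuclear) channels; the physical pixel size comes from a YAML
sidecar or an explicit argument, never from image metadata.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ExpressionMatrix,
    RatioScore,
    StainImage,
    SurvivalRecord,
    ViabilityRecord,
    normalize_symbol,
)
from .errors import FormatError, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_viability",
    "read_image",
    "write_image",
    "write_scores",
    "read_scores",
    "read_config",
]

SCORE_COLUMNS = [
    "gene_of_interest",
    "signature_name",
    "direction",
    "numerator",
    "denominator",
    "ratio",
    "missing_genes",
    "self_excluded",
]


def _sniff_sep(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression(
    path: str | Path,
    groups_path: str | Path | None = None,
    group_column: str = "group",
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Parameters
    ----------
    path
        TSV/CSV file: first column gene symbols, header row sample ids.
    groups_path
        Optional companion table mapping ``sample_id`` to a subgroup label
        (column name given by *group_column*).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"expression table {path} is empty")
    symbols = [normalize_symbol(g) for g in df.index]
    dupes = sorted({g for g in symbols if symbols.count(g) > 1})
    if dupes:
        raise FormatError(f"duplicate gene symbols in {path}: {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]].tolist()
        raise FormatError(f"non-numeric expression values in columns {bad} of {path}")
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(Path(groups_path), sep=_sniff_sep(Path(groups_path)))
        if "sample_id" not in gdf.columns or group_column not in gdf.columns:
            raise FormatError(
                f"groups table must have 'sample_id' and {group_column!r} columns"
            )
        groups = dict(zip(gdf["sample_id"].astype(str), gdf[group_column].astype(str)))
        groups = {s: g for s, g in groups.items() if s in set(map(str, df.columns))}
    return ExpressionMatrix(
        gene_ids=symbols,
        sample_ids=[str(c) for c in df.columns],
        values=values,
        sample_groups=groups,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    expr.to_frame().to_csv(Path(path), sep=sep, index_label="gene")
    if expr.sample_groups:
        side = Path(path).with_suffix(".groups.csv")
        pd.DataFrame(
            {"sample_id": list(expr.sample_groups), "group": list(expr.sample_groups.values())}
        ).to_csv(side, index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival CSV with subject_id, time_days, event, group columns."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"subject_id", "time_days", "event", "group"}
    if not required.issubset(df.columns):
        raise FormatError(f"survival table needs columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        ev = row["event"]
        if ev not in (0, 1, True, False):
            raise FormatError(f"event must be 0/1, got {ev!r}")
        t = float(row["time_days"])
        if not np.isfinite(t) or t <= 0:
            raise FormatError(f"time_days must be > 0, got {t}")
        records.append(
            SurvivalRecord(
                subject_id=str(row["subject_id"]),
                time_days=t,
                event=bool(ev),
                group=str(row["group"]),
            )
        )
    return records


def write_survival(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time_days": [r.time_days for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    ).to_csv(Path(path), index=False)


def read_viability(path: str | Path) -> list[ViabilityRecord]:
    """Read an MTT plate CSV: treatment_label, dose_uM, timepoint_h, od_540, od_650."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"treatment_label", "dose_uM", "timepoint_h", "od_540", "od_650"}
    if not required.issubset(df.columns):
        raise FormatError(f"viability table needs columns {sorted(required)}")
    return [
        ViabilityRecord(
            treatment_label=str(r["treatment_label"]),
            dose_uM=float(r["dose_uM"]),
            timepoint_h=int(r["timepoint_h"]),
            od_540=float(r["od_540"]),
            od_650=float(r["od_650"]),
        )
        for _, r in df.iterrows()
    ]


def read_image(path: str | Path, pixel_size_um: float | None = None) -> StainImage:
    """Read a 1- or 2-channel TIFF/PNG as a StainImage.

    Two-channel images are interpreted as (marker, nuclear) in channel order;
    single-channel images are nuclear-only (``has_marker`` False). The pixel
    size is taken from *pixel_size_um*, or from a ``<stem>.meta.yaml`` sidecar
    with a ``pixel_size_um`` key, defaulting to 1 um/px.
    """
    import imageio.v3 as iio

    path = Path(path)
    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 2:
        marker, nuclear = None, arr
    elif arr.ndim == 3:
        # channel axis may be first (CYX tiff) or last (YXC png)
        if arr.shape[0] in (1, 2) and arr.shape[0] < min(arr.shape[1:]):
            channels = [arr[i] for i in range(arr.shape[0])]
        elif arr.shape[-1] in (1, 2):
            channels = [arr[..., i] for i in range(arr.shape[-1])]
        else:
            raise FormatError(
                f"{path}: expected 1 or 2 channels, got shape {arr.shape}"
            )
        if len(channels) == 1:
            marker, nuclear = None, channels[0]
        else:
            marker, nuclear = channels
    else:
        raise FormatError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if pixel_size_um is None:
        sidecar = path.with_suffix("").with_suffix(".meta.yaml")
        if not sidecar.exists():
            sidecar = path.parent / (path.stem + ".meta.yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            pixel_size_um = float(meta.get("pixel_size_um", 1.0))
        else:
            pixel_size_um = 1.0
    return StainImage(marker=marker, nuclear=nuclear, pixel_size_um=pixel_size_um)


def write_image(image: StainImage, path: str | Path) -> None:
    """Write a StainImage as a float32 TIFF (channel-first when two channels)
    plus a YAML sidecar recording the pixel size."""
    import tifffile

    path = Path(path)
    if image.marker is None:
        data = image.nuclear.astype(np.float32)
    else:
        data = np.stack([image.marker, image.nuclear]).astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = path.parent / (path.stem + ".meta.yaml")
    sidecar.write_text(yaml.safe_dump({"pixel_size_um": float(image.pixel_size_um)}))


def write_scores(scores: Iterable[RatioScore], path: str | Path) -> None:
    """Write RatioScores as a long-format TSV (lossless round trip)."""
    rows = []
    for s in scores:
        rows.append(
            {
                "gene_of_interest": s.gene_of_interest,
                "signature_name": s.signature_name,
                "direction": s.direction,
                "numerator": s.numerator,
                "denominator": s.denominator,
                "ratio": repr(s.ratio),
                "missing_genes": ";".join(s.missing_genes),
                "self_excluded": int(s.self_excluded),
            }
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=SCORE_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_scores(path: str | Path) -> list[RatioScore]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        scores = []
        for row in reader:
            scores.append(
                RatioScore(
                    gene_of_interest=row["gene_of_interest"],
                    signature_name=row["signature_name"],
                    direction=row["direction"],
                    numerator=int(row["numerator"]),
                    denominator=int(row["denominator"]),
                    ratio=float(row["ratio"]),
                    missing_genes=tuple(
                        g for g in row["missing_genes"].split(";") if g
                    ),
                    self_excluded=bool(int(row["self_excluded"])),
                )
            )
    return scores


def read_config(path: str | Path) -> dict:
    """Read a YAML config (thresholds, seeds, pixel sizes)."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data
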