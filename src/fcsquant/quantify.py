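"""Promoter-strength quantification from fluorescence images.

Mirrors the standard widefield/confocal workflow for ranking expression
constructs: subtract a background measured on non-transfected cells (or a
designated cell-free region), average the corrected intensity over each
whole-cell region of interest (bright foci included), summarize per
promoter construct over at least 10 cells as mean +/- SD, and rescale so a
designated reference construct reads a fixed value (10 by convention).
Constructs whose cells saturate the detector are flagged out of range and
excluded from the normalized comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .images import CellImage

__all__ = [
    "IntensityRecord",
    "PromoterSummary",
    "PromoterComparison",
    "subtract_background",
    "measure_cells",
    "summarize_promoters",
    "compare_promoters",
]

#: fraction of mask pixels at the bit-depth maximum that marks saturation
SATURATION_FRACTION = 0.01

#: minimum cells per construct for a reportable summary
MIN_CELLS = 10


@dataclass
class IntensityRecord:
    """Background-corrected mean intensity of one cell."""

    cell_id: int
    promoter_label: str
    mean_intensity: float
    n_pixels: int
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        if not np.isfinite(self.mean_intensity):
            raise ValueError("mean_intensity must be finite")


@dataclass
class PromoterSummary:
    """Per-construct summary over cells (mean +/- SD, reference-scaled)."""

    promoter_label: str
    n_cells: int
    mean: float
    sd: float
    normalized_mean: float
    reportable: bool
    out_of_range: bool


@dataclass
class PromoterComparison:
    """Welch two-sample comparison of two constructs' per-cell means."""

    label_a: str
    label_b: str
    ratio: float  # mean_a / mean_b
    p_value: float
    n_a: int
    n_b: int


def subtract_background(
    image: Union[CellImage, np.ndarray],
    background_value: Optional[float] = None,
    *,
    background_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pixelwise background subtraction, clipped at zero.

    ``background_value`` may be supplied directly (e.g. measured on
    non-transfected cells) or estimated as the mean of a designated
    non-cell region: ``background_mask`` if given, else all unmasked
    pixels of a :class:`CellImage`.
    """
    if isinstance(image, CellImage):
        pixels = np.asarray(image.pixels, dtype=float)
        if background_value is None and background_mask is None:
            background_mask = image.masks == 0
    else:
        pixels = np.asarray(image, dtype=float)
    if background_value is None:
        if background_mask is None:
            raise ValueError(
                "supply background_value or background_mask (or a CellImage)"
            )
        if not background_mask.any():
            raise ValueError("background_mask selects no pixels")
        background_value = float(pixels[background_mask].mean())
    if background_value < 0:
        raise ValueError("background_value must be non-negative")
    if background_value > pixels.mean():
        warnings.warn(
            f"background ({background_value:.1f}) exceeds the global image "
            f"mean ({pixels.mean():.1f}); corrected intensities will be "
            "dominated by clipping",
            stacklevel=2,
        )
    return np.clip(pixels - background_value, 0.0, None)


def measure_cells(
    image: CellImage,
    background_value: Optional[float] = None,
    *,
    saturation_fraction: float = SATURATION_FRACTION,
) -> list[IntensityRecord]:
    """One background-corrected record per cell mask (foci included).

    The whole cell is the region of interest: the mean runs over every
    mask pixel.  A cell is flagged saturated when at least
    ``saturation_fraction`` of its raw pixels sit at the bit-depth
    maximum.  Empty masks are skipped with a warning.
    """
    corrected = subtract_background(image, background_value)
    depth = 16
    cfg = image.metadata.get("config") if image.metadata else None
    if cfg and "pixel_depth" in cfg:
        depth = int(cfg["pixel_depth"])
    max_val = 2**depth - 1
    raw = np.asarray(image.pixels)

    records: list[IntensityRecord] = []
    for cid in range(1, image.n_cells + 1):
        mask = image.masks == cid
        n_px = int(mask.sum())
        if n_px == 0:
            warnings.warn(f"cell {cid} has an empty mask; skipped", stacklevel=2)
            continue
        label = ""
        if image.ground_truth is not None and len(image.ground_truth):
            row = image.ground_truth[image.ground_truth.cell_id == cid]
            if len(row):
                label = str(row.promoter_label.iloc[0])
        sat = float((raw[mask] >= max_val).mean()) >= saturation_fraction
        records.append(
            IntensityRecord(
                cell_id=cid,
                promoter_label=label,
                mean_intensity=float(corrected[mask].mean()),
                n_pixels=n_px,
                saturated=sat,
            )
        )
    return records


def summarize_promoters(
    records: Sequence[IntensityRecord],
    reference_label: str,
    reference_value: float = 10.0,
    *,
    min_cells: int = MIN_CELLS,
    saturated_majority: float = 0.5,
) -> list[PromoterSummary]:
    """Per-construct mean +/- SD, rescaled so the reference reads
    ``reference_value``.

    A construct needs at least ``min_cells`` cells to be reportable; a
    construct in which more than ``saturated_majority`` of cells saturate
    the detector is flagged out of range and carries no normalized mean.
    """
    if not records:
        raise ValueError("no records to summarize")
    by_label: dict[str, list[IntensityRecord]] = {}
    for r in records:
        by_label.setdefault(r.promoter_label, []).append(r)

    if reference_label not in by_label:
        raise ValueError(f"reference label {reference_label!r} absent")
    ref_recs = by_label[reference_label]
    if len(ref_recs) < min_cells:
        raise ValueError(
            f"reference label {reference_label!r} has {len(ref_recs)} cells; "
            f"needs >= {min_cells}"
        )
    ref_mean = float(np.mean([r.mean_intensity for r in ref_recs]))
    if ref_mean <= 0:
        raise ValueError("reference construct has non-positive mean intensity")

    out = []
    for label, recs in by_label.items():
        vals = np.array([r.mean_intensity for r in recs])
        sat_frac = np.mean([r.saturated for r in recs])
        out_of_range = bool(sat_frac > saturated_majority)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            PromoterSummary(
                promoter_label=label,
                n_cells=len(recs),
                mean=mean,
                sd=sd,
                normalized_mean=(
                    float("nan") if out_of_range
                    else mean * reference_value / ref_mean
                ),
                reportable=len(recs) >= min_cells and not out_of_range,
                out_of_range=out_of_range,
            )
        )
    out.sort(key=lambda s: s.promoter_label)
    return out


def compare_promoters(
    records_a: Sequence[Union[IntensityRecord, float]],
    records_b: Sequence[Union[IntensityRecord, float]],
    label_a: str = "A",
    label_b: str = "B",
) -> PromoterComparison:
    """Welch's unequal-variance t-test on two constructs' per-cell means.

    Returns the effect size as the ratio of means together with the
    two-sided p-value.  With zero variance in both groups the test is
    degenerate and only the ratio is reported (p = NaN).
    """

    def _vals(recs):
        return np.array(
            [r.mean_intensity if isinstance(r, IntensityRecord) else float(r)
             for r in recs]
        )

    a, b = _vals(records_a), _vals(records_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two cells per group")
    if isinstance(records_a[0], IntensityRecord):
        label_a = records_a[0].promoter_label or label_a
    if isinstance(records_b[0], IntensityRecord):
        label_b = records_b[0].promoter_label or label_b
    mean_b = b.mean()
    ratio = float(a.mean() / mean_b) if mean_b != 0 else float("inf")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = float("nan")
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return PromoterComparison(
        label_a=label_a, label_b=label_b, ratio=ratio, p_value=p,
        n_a=int(a.size), n_b=int(b.size),
    )
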