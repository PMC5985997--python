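"""Synthetic fluorescence-microscopy images with known expression ground truth.

Emulates the image material used for promoter-strength ranking: adherent
cells with spatially uniform cytosolic fluorescence on a uniform camera
background with Gaussian read noise, optionally decorated with a few small
bright foci (e.g. microtubule organizing centers or membrane ruffles) that
belong to the cell and are included in whole-cell quantification but must
be avoided when positioning an FCS observation volume.

Per-cell expression levels follow either an explicit list of plateau
intensities or a log-normal law per promoter label (median and geometric
sigma), reflecting the broad cell-to-cell variability of transient
transfection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

__all__ = ["ImageSimConfig", "CellImage", "simulate_cell_image"]

IntensityLaw = Union[Sequence[float], dict[str, tuple[float, float]]]


@dataclass
class ImageSimConfig:
    """Configuration of one synthetic cell image.

    ``cell_mean_intensities`` is either one plateau value per cell (counts
    above background) or a mapping ``label -> (median, sigma)`` of a
    log-normal law from which per-cell plateaus are drawn.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_depth: int = 16
    background_level: float = 100.0
    noise_sd: float = 5.0
    n_cells: int = 0
    cell_mean_intensities: Optional[IntensityLaw] = None
    promoter_labels: Sequence[str] = ()
    foci_per_cell: int = 0
    foci_amplitude: float = 0.0
    cell_radius_range: tuple[float, float] = (25.0, 40.0)
    foci_radius: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) != 2 or min(self.image_shape) < 16:
            raise ValueError("image_shape must be 2-D, at least 16x16")
        if self.pixel_depth not in (8, 12, 16):
            raise ValueError("pixel_depth must be 8, 12 or 16")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.n_cells != len(self.promoter_labels):
            raise ValueError("promoter_labels must have one entry per cell")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background_level and noise_sd must be >= 0")
        if self.foci_per_cell < 0 or self.foci_amplitude < 0:
            raise ValueError("foci settings must be >= 0")
        if isinstance(self.cell_mean_intensities, dict):
            for lbl, (med, sig) in self.cell_mean_intensities.items():
                if med < 0 or sig < 0:
                    raise ValueError(f"invalid log-normal law for {lbl!r}")
        elif self.cell_mean_intensities is not None:
            vals = list(self.cell_mean_intensities)
            if len(vals) != self.n_cells:
                raise ValueError("need one intensity per cell")
            if any(v < 0 for v in vals):
                raise ValueError("intensities must be >= 0")


@dataclass
class CellImage:
    """Synthetic frame, per-cell masks, and the programmed ground truth.

    ``masks`` is a label image (0 = background, i = cell i); ``foci_mask``
    marks the bright foci so FCS-placement code can avoid them.
    ``ground_truth`` has columns cell_id, promoter_label,
    true_mean_above_background (foci-inclusive in-mask expectation).
    """

    pixels: np.ndarray
    masks: np.ndarray
    ground_truth: pd.DataFrame
    foci_mask: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.masks = np.asarray(self.masks)
        if self.pixels.shape != self.masks.shape:
            raise ValueError("pixels and masks must share a shape")

    @property
    def n_cells(self) -> int:
        return int(self.masks.max())

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.masks == cell_id


def _draw_intensities(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.cell_mean_intensities is None:
        raise ValueError("cell_mean_intensities is required when n_cells > 0")
    if isinstance(cfg.cell_mean_intensities, dict):
        law = cfg.cell_mean_intensities
        vals = np.empty(cfg.n_cells)
        for i, lbl in enumerate(cfg.promoter_labels):
            if lbl not in law:
                raise ValueError(f"no intensity law for label {lbl!r}")
            med, sig = law[lbl]
            vals[i] = med * np.exp(sig * rng.standard_normal())
        return vals
    return np.asarray(list(cfg.cell_mean_intensities), dtype=float)


def simulate_cell_image(config: ImageSimConfig) -> CellImage:
    """Render the image and return it with masks and ground truth.

    Cells are ellipses with random axes and orientation placed without
    overlap (bounded retries; raises if the field is too crowded).
    Reproducible for a given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    masks = np.zeros((h, w), dtype=np.uint16)
    foci_mask = np.zeros((h, w), dtype=bool)
    plateau = np.zeros((h, w), dtype=float)

    intensities = (
        _draw_intensities(config, rng) if config.n_cells else np.empty(0)
    )

    rows = []
    max_tries = 200
    r_lo, r_hi = config.cell_radius_range
    for i in range(config.n_cells):
        placed = False
        for _ in range(max_tries):
            a = rng.uniform(r_lo, r_hi)
            b = rng.uniform(r_lo, r_hi)
            theta = rng.uniform(0, np.pi)
            margin = max(a, b) + 2
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
            if masks[rr, cc].any():
                continue
            # demand one blank pixel of separation between cells
            clear = masks[max(0, rr.min() - 1): rr.max() + 2,
                          max(0, cc.min() - 1): cc.max() + 2]
            if clear.any():
                continue
            masks[rr, cc] = i + 1
            plateau[rr, cc] += intensities[i]
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1} without overlap "
                f"after {max_tries} tries"
            )
        cell_px = int(len(rr))
        foci_px = 0
        if config.foci_per_cell and config.foci_amplitude > 0:
            in_cell = np.flatnonzero(masks == i + 1)
            for _ in range(config.foci_per_cell):
                k = in_cell[rng.integers(len(in_cell))]
                fy, fx = divmod(int(k), w)
                fr, fc = disk((fy, fx), config.foci_radius, shape=(h, w))
                keep = masks[fr, fc] == i + 1
                fr, fc = fr[keep], fc[keep]
                plateau[fr, fc] += config.foci_amplitude
                new = ~foci_mask[fr, fc]
                foci_px += int(new.sum())
                foci_mask[fr, fc] = True
        # exact expectation of the in-mask mean above background, foci included
        foci_excess = (
            plateau[masks == i + 1].mean() - intensities[i]
            if config.foci_per_cell else 0.0
        )
        rows.append(
            {
                "cell_id": i + 1,
                "promoter_label": config.promoter_labels[i],
                "true_mean_above_background": intensities[i] + foci_excess,
                "n_pixels": cell_px,
                "n_foci_pixels": foci_px,
            }
        )

    img = plateau + config.background_level
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    max_val = 2**config.pixel_depth - 1
    pixels = np.clip(np.rint(img), 0, max_val).astype(np.uint16)

    gt = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "promoter_label", "true_mean_above_background",
            "n_pixels", "n_foci_pixels",
        ],
    )
    return CellImage(
        pixels=pixels,
        masks=masks,
        ground_truth=gt,
        foci_mask=foci_mask,
        metadata={"config": {k: v for k, v in vars(config).items()},
                  "seed": config.seed},
    )
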