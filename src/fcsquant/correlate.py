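"""Normalized fluctuation autocorrelation of an intensity trace.

The autocorrelation of a fluorescence trace F(t) is defined as

    G(tau) = < dF(t) dF(t+tau) > / <F>^2 ,      dF = F - <F>,

i.e. the time-lagged self-covariance of the fluctuations normalized by the
square of the mean intensity, so that G decays to 0 at long lags and its
amplitude is inversely proportional to the mean number of molecules in the
observation volume.

Two estimators are provided:

``autocorrelate_direct``
    Brute-force linear-lag estimator, exact to floating precision.  Serves
    as the oracle for the production path and for short traces.

``autocorrelate_multitau``
    The standard multi-tau scheme of hardware correlators: a quasi-
    logarithmic lag grid in which the signal is pairwise-rebinned every
    octave, so 20-s traces at microsecond bins correlate in O(n) time over
    six decades of lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .traces import IntensityTrace

__all__ = [
    "CorrelationCurve",
    "autocorrelate_direct",
    "autocorrelate_multitau",
]


@dataclass
class CorrelationCurve:
    """Lag times (s) and normalized autocorrelation values G(tau)."""

    lags: np.ndarray
    g: np.ndarray
    g_err: Optional[np.ndarray] = None
    n_samples: Optional[np.ndarray] = None
    source: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have the same length")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.lags.size and self.lags[0] < 0:
            raise ValueError("lags must be non-negative")
        if self.g_err is not None:
            self.g_err = np.asarray(self.g_err, dtype=float)
            if self.g_err.shape != self.g.shape:
                raise ValueError("g_err length mismatch")
        if self.n_samples is not None:
            self.n_samples = np.asarray(self.n_samples)
            if self.n_samples.shape != self.g.shape:
                raise ValueError("n_samples length mismatch")

    def __len__(self) -> int:
        return int(self.lags.size)

    def restrict(self, lag_min: float = 0.0, lag_max: float = np.inf) -> "CorrelationCurve":
        """Return the sub-curve with lag_min <= lag <= lag_max."""
        m = (self.lags >= lag_min) & (self.lags <= lag_max)
        return CorrelationCurve(
            self.lags[m],
            self.g[m],
            None if self.g_err is None else self.g_err[m],
            None if self.n_samples is None else self.n_samples[m],
            dict(self.source),
        )


def _fluctuations(trace: IntensityTrace) -> tuple[np.ndarray, float]:
    c = np.asarray(trace.counts, dtype=float)
    mean = c.mean() if c.size else 0.0
    if mean == 0.0:
        raise ValueError("trace has zero mean intensity; G is undefined")
    return c - mean, mean


def autocorrelate_direct(
    trace: IntensityTrace,
    max_lag: float,
    *,
    circular: bool = False,
    include_zero: bool = False,
) -> CorrelationCurve:
    """Brute-force autocorrelation on a linear lag grid.

    Parameters
    ----------
    trace : IntensityTrace
    max_lag : float
        Largest lag in seconds; must be smaller than the trace duration.
    circular : bool
        Treat the trace as one period of a periodic signal (products wrap
        around).  Only meaningful for synthetic periodic fixtures; real
        acquisitions are finite stationary segments and use the truncated
        (non-circular) convention.
    include_zero : bool
        Include the zero-lag point G(0) (variance over mean squared).
    """
    n = trace.n_bins
    if n < 2:
        raise ValueError("trace must have at least 2 bins")
    k_max = int(np.floor(max_lag / trace.bin_width + 1e-9))
    if k_max >= n:
        raise ValueError("max_lag must be smaller than the trace duration")
    k_max = max(k_max, 1)
    d, mean = _fluctuations(trace)

    ks = np.arange(0 if include_zero else 1, k_max + 1)
    g = np.empty(ks.size)
    n_samp = np.empty(ks.size, dtype=np.int64)
    for i, k in enumerate(ks):
        if circular:
            prod = d @ np.roll(d, -k)
            cnt = n
        else:
            prod = d[: n - k] @ d[k:]
            cnt = n - k
        g[i] = prod / cnt / mean**2
        n_samp[i] = cnt
    lags = ks * trace.bin_width
    return CorrelationCurve(
        lags, g, None, n_samp,
        source={"estimator": "direct", "circular": circular,
                "bin_width": trace.bin_width, "n_bins": n},
    )


def multitau_lag_bins(points_per_octave: int, max_lag_bins: int) -> list[tuple[int, int]]:
    """Lag grid of the multi-tau scheme as (level, lag-in-level-bins) pairs.

    Level 0 holds ``points_per_octave`` linearly spaced lags (1..m bins);
    every further level rebins the signal by 2 and holds the upper half of
    the octave (m/2+1 .. m), so the absolute lag spacing doubles per octave.
    """
    m = points_per_octave
    grid: list[tuple[int, int]] = []
    for k in range(1, m + 1):
        if k <= max_lag_bins:
            grid.append((0, k))
    level = 1
    while (m // 2 + 1) * 2**level <= max_lag_bins:
        for k in range(m // 2 + 1, m + 1):
            if k * 2**level <= max_lag_bins:
                grid.append((level, k))
        level += 1
    return grid


def _multitau_raw(
    counts: np.ndarray, grid: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized multi-tau machinery: per-lag G and sample counts.

    Normalization per level uses the level series' own mean, which for even
    truncation equals the global mean; within level 0 (no rebinning) the
    estimator is bitwise the direct one.
    """
    g = np.full(len(grid), np.nan)
    n_samp = np.zeros(len(grid), dtype=np.int64)
    level_data = np.asarray(counts, dtype=float)
    level = 0
    i = 0
    while i < len(grid):
        entries = [(j, k) for j, (lv, k) in enumerate(grid) if lv == level]
        n = level_data.size
        mean = level_data.mean() if n else 0.0
        d = level_data - mean
        for j, k in entries:
            if k < n and mean != 0.0:
                g[j] = (d[: n - k] @ d[k:]) / (n - k) / mean**2
                n_samp[j] = n - k
        i += len(entries)
        # pairwise rebin for the next octave
        half = (level_data.size // 2) * 2
        level_data = level_data[:half].reshape(-1, 2).sum(axis=1)
        level += 1
        if level_data.size < 2:
            break
    return g, n_samp


def autocorrelate_multitau(
    trace: IntensityTrace,
    points_per_octave: int = 8,
    max_lag: Optional[float] = None,
    *,
    n_error_blocks: int = 0,
) -> CorrelationCurve:
    """Multi-tau autocorrelation on a quasi-logarithmic lag grid.

    Parameters
    ----------
    points_per_octave : int
        Number of lags per octave (>= 4, even).  Within the first octave no
        rebinning occurs and the values equal ``autocorrelate_direct``.
    max_lag : float, optional
        Largest lag in seconds; defaults to a tenth of the trace duration
        (the long-lag estimator variance grows past that point).
    n_error_blocks : int
        If > 1, the trace is split into this many contiguous blocks and the
        per-lag standard error of the block estimates is reported in
        ``g_err`` (NaN where a block is too short for the lag).
    """
    if points_per_octave < 4:
        raise ValueError("points_per_octave must be >= 4")
    if points_per_octave % 2:
        raise ValueError("points_per_octave must be even")
    n = trace.n_bins
    if n < 2:
        raise ValueError("trace must have at least 2 bins")
    if max_lag is None:
        max_lag = trace.duration / 10.0
    max_lag_bins = min(int(np.floor(max_lag / trace.bin_width + 1e-9)), n - 1)
    if max_lag_bins < 1:
        raise ValueError("max_lag must cover at least one bin")
    _fluctuations(trace)  # zero-mean check

    grid = multitau_lag_bins(points_per_octave, max_lag_bins)
    g, n_samp = _multitau_raw(np.asarray(trace.counts), grid)
    lags = np.array([k * 2**lv for lv, k in grid]) * trace.bin_width

    g_err = None
    if n_error_blocks > 1:
        block_len = n // n_error_blocks
        if block_len >= 2:
            blocks = np.full((n_error_blocks, len(grid)), np.nan)
            for b in range(n_error_blocks):
                seg = np.asarray(trace.counts[b * block_len:(b + 1) * block_len])
                if seg.size and seg.mean() > 0:
                    gb, nb = _multitau_raw(seg, grid)
                    # demand a minimal number of products per block estimate
                    gb[nb < 8] = np.nan
                    blocks[b] = gb
            n_ok = np.sum(np.isfinite(blocks), axis=0)
            g_err = np.full(len(grid), np.nan)
            ok = n_ok > 1
            if ok.any():
                with np.errstate(invalid="ignore"):
                    g_err[ok] = (
                        np.nanstd(blocks[:, ok], axis=0, ddof=1)
                        / np.sqrt(n_ok[ok])
                    )

    keep = np.isfinite(g)
    return CorrelationCurve(
        lags[keep], g[keep],
        None if g_err is None else g_err[keep],
        n_samp[keep],
        source={"estimator": "multitau", "points_per_octave": points_per_octave,
                "bin_width": trace.bin_width, "n_bins": n,
                "n_error_blocks": n_error_blocks},
    )
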