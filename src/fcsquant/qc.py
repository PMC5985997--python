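"""Trace acceptance screening and FCS-suitability assessment.

Traces from molecules confined in compartments, colliding with organelles,
or otherwise not diffusing freely show slow drifts or oscillations of the
count rate; such acquisitions must be excluded before correlation analysis.
The screen compares segment-mean statistics of a trace against what a
stationary shot-noise-limited signal would produce.

Separately, an expression level is judged suitable for FCS when the mean
number of molecules in the observation volume falls in an optimal band
(default 5-20): below it the signal is too dim, above it the relative
fluctuations are too small against detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .traces import IntensityTrace

__all__ = [
    "QCReport",
    "SuitabilityVerdict",
    "screen_trace",
    "assess_suitability",
]

#: segments for the slow-drift statistic
DRIFT_SEGMENTS = 10

#: segments for the oscillation statistic; finer than the drift grid so
#: rate modulations up to ~ (segments / 2) cycles per trace are visible
OSCILLATION_SEGMENTS = 50


@dataclass
class QCReport:
    """Outcome of the stationarity screen of one trace."""

    accepted: bool
    drift_fraction: float
    oscillation_score: float
    reasons: list[str]
    drift_threshold: float
    oscillation_threshold: float


@dataclass
class SuitabilityVerdict:
    """Expression-level verdict from the fitted molecule number."""

    n_estimate: float
    verdict: Literal["too_dim", "optimal", "too_bright"]
    optimal_band: tuple[float, float]


def _segment_means(counts: np.ndarray, n_seg: int) -> tuple[np.ndarray, int]:
    seg_len = counts.size // n_seg
    segs = counts[: seg_len * n_seg].reshape(n_seg, seg_len)
    return segs.mean(axis=1), seg_len


def screen_trace(
    trace: IntensityTrace,
    drift_threshold: float = 0.2,
    oscillation_threshold: float = 3.0,
    *,
    oscillation_segments: int = OSCILLATION_SEGMENTS,
) -> QCReport:
    """Screen a trace for slow drifts and oscillations of the count rate.

    Two statistics are formed from segment means of the counts-per-bin
    signal and the global mean m:

    - ``drift_fraction``: over 10 equal segments,
      (max segment mean - min segment mean) / m — the peak-to-peak
      relative excursion of the local rate;
    - ``oscillation_score``: over a finer grid (50 segments by default, so
      modulations up to ~25 cycles per trace are inside the passband),
      the variance of the segment means divided by its expectation for a
      *stationary* trace.  That expectation is estimated from within-
      segment statistics (each segment is split into 10 sub-segments and
      the scaled variance of sub-segment means is pooled), floored at the
      pure shot-noise value m / L for segments of L bins.

    The within-segment denominator matters: a healthy FCS trace is not
    shot-noise limited at low frequencies — molecular number fluctuations
    carry genuine excess power at all timescales up to the diffusion
    time — so normalizing by shot noise alone would reject perfectly
    stationary single-molecule traces.  Fluctuations much faster than a
    segment enter numerator and denominator alike (score near 1), while
    drifts and modulations slower than a few segments inflate only the
    numerator.

    The trace is accepted iff both statistics are below their thresholds.
    """
    counts = np.asarray(trace.counts, dtype=float)
    if counts.size < DRIFT_SEGMENTS:
        raise ValueError(f"trace must have at least {DRIFT_SEGMENTS} bins")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("trace has zero mean; screening is undefined")

    drift_means, _ = _segment_means(counts, DRIFT_SEGMENTS)
    drift = float((drift_means.max() - drift_means.min()) / mean)

    n_sub = 10
    n_osc = max(DRIFT_SEGMENTS, min(oscillation_segments,
                                    counts.size // DRIFT_SEGMENTS))
    osc_means, seg_len = _segment_means(counts, n_osc)
    shot_var = mean / seg_len  # Poisson variance of a segment mean
    stationary_var = shot_var
    if seg_len >= 2 * n_sub:
        sub_len = seg_len // n_sub
        used = n_osc * n_sub * sub_len
        subs = counts[:used].reshape(n_osc, n_sub, sub_len).mean(axis=2)
        # variance of a segment mean implied by independent sub-segments
        within = float(np.mean(subs.var(axis=1, ddof=1))) / n_sub
        stationary_var = max(within, shot_var)
    osc = float(osc_means.var(ddof=1) / stationary_var)

    reasons = []
    if drift >= drift_threshold:
        reasons.append(
            f"drift: segment-mean excursion {drift:.3f} >= {drift_threshold}"
        )
    if osc >= oscillation_threshold:
        reasons.append(
            f"oscillation: segment-mean variance {osc:.2f}x the stationary "
            f"expectation >= {oscillation_threshold}x"
        )
    return QCReport(
        accepted=not reasons,
        drift_fraction=drift,
        oscillation_score=osc,
        reasons=reasons,
        drift_threshold=drift_threshold,
        oscillation_threshold=oscillation_threshold,
    )


def assess_suitability(
    n_estimate: float,
    optimal_band: tuple[float, float] = (5.0, 20.0),
) -> SuitabilityVerdict:
    """Judge whether an expression level suits FCS (default band 5-20)."""
    if not (n_estimate > 0):
        raise ValueError("n_estimate must be positive")
    lo, hi = optimal_band
    if not (0 < lo < hi):
        raise ValueError("optimal_band must be an increasing positive interval")
    if n_estimate < lo:
        verdict = "too_dim"
    elif n_estimate > hi:
        verdict = "too_bright"
    else:
        verdict = "optimal"
    return SuitabilityVerdict(float(n_estimate), verdict, (lo, hi))
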