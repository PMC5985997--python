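"""Binned photon-count time traces, the raw FCS observable.

An FCS acquisition is a photon-count time series F(t): the detector output
integrated over contiguous bins of fixed width.  Everything downstream
(correlation, model fitting, quality screening) consumes this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["IntensityTrace"]


@dataclass
class IntensityTrace:
    """A binned fluorescence-intensity time series.

    Parameters
    ----------
    counts : ndarray of int
        Photon counts per bin, all non-negative.
    bin_width : float
        Bin width in seconds.
    metadata : dict
        Provenance (simulation config echo, seed, source file, ...).
    """

    counts: np.ndarray
    bin_width: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        """Total acquisition time in seconds."""
        return self.n_bins * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Left edge of each bin, in seconds."""
        return np.arange(self.n_bins) * self.bin_width

    def mean_rate(self) -> float:
        """Mean count rate in photons/s."""
        return float(self.counts.mean() / self.bin_width)

    def rebin(self, factor: int) -> "IntensityTrace":
        """Sum adjacent bins by an integer factor (tail bins dropped)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        n = (self.n_bins // factor) * factor
        c = self.counts[:n].reshape(-1, factor).sum(axis=1)
        return IntensityTrace(c, self.bin_width * factor, dict(self.metadata))
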