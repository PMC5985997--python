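"""Shared fixtures: small simulated ensembles reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fcsquant.correlate import autocorrelate_multitau
from fcsquant.simulate import TraceSimConfig, simulate_diffusion_trace


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_short_config(**overrides) -> TraceSimConfig:
    """1-s acquisition at 10-us bins, otherwise the standard eGFP geometry."""
    kwargs = dict(
        mean_occupancy=5.0,
        diff_coeff=35.4,
        brightness=5e3,
        triplet_fraction=0.0,
        duration=1.0,
        bin_width=1e-5,
        time_step=1e-5,
        seed=0,
    )
    kwargs.update(overrides)
    return TraceSimConfig(**kwargs)


@pytest.fixture(scope="session")
def short_trace_ensemble():
    """15 short traces at occupancy 5, T = 0, with their multi-tau curves."""
    traces, curves = [], []
    for seed in range(15):
        cfg = make_short_config(seed=seed)
        tr = simulate_diffusion_trace(cfg)
        traces.append(tr)
        curves.append(autocorrelate_multitau(tr, 8, 0.05, n_error_blocks=5))
    return {"config": make_short_config(), "traces": traces, "curves": curves}


@pytest.fixture(scope="session")
def poisson_trace(rng):
    """Stationary shot-noise-limited trace: rate 1e5/s, 2 s at 0.1-ms bins."""
    from fcsquant.traces import IntensityTrace

    counts = rng.poisson(10.0, size=20_000)
    return IntensityTrace(counts, 1e-4, {"rate": 1e5})
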