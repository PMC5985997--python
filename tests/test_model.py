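"""Model, fitting, calibration, and derived-quantity tests.

Closed-form values are frozen from hand arithmetic on the model
definition; fitting tests check self-consistency on noise-free curves.
"""

from __future__ import annotations

import numpy as np
import pytest

from fcsquant.correlate import CorrelationCurve
from fcsquant.model import (
    FcsModelParams,
    analytic_acf,
    calibrate_volume,
    concentration,
    derive_quantities,
    diffusion_coefficient,
    effective_volume,
    fit_curve,
)

LAGS = np.geomspace(1e-6, 0.1, 120)


class TestAnalyticAcf:
    def test_zero_lag_amplitude_is_inverse_n(self):
        c = analytic_acf(FcsModelParams(10.0, 1e-4), [0.0])
        assert c.g[0] == pytest.approx(0.1, rel=1e-12)

    def test_value_at_diffusion_time(self):
        # t = tau_D, S = 5: (1/2) * (1 + 1/25)^(-1/2) = 0.490290...
        p = FcsModelParams(1.0, 1e-3, aspect_ratio=5.0)
        c = analytic_acf(p, [1e-3])
        assert c.g[0] == pytest.approx(0.5 * (1 + 1 / 25) ** -0.5, rel=1e-12)
        assert c.g[0] == pytest.approx(0.4903, abs=5e-5)

    def test_triplet_amplitude_boost(self):
        # N=5, T=0.2 at t=0: (1/5)(1 + 0.25) = 0.25
        p = FcsModelParams(5.0, 1e-4, triplet_fraction=0.2)
        c = analytic_acf(p, [0.0])
        assert c.g[0] == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_molecules": 0.0, "diffusion_time": 1e-4},
            {"n_molecules": -1.0, "diffusion_time": 1e-4},
            {"n_molecules": 1.0, "diffusion_time": 0.0},
            {"n_molecules": 1.0, "diffusion_time": 1e-4,
             "triplet_fraction": 1.0},
            {"n_molecules": 1.0, "diffusion_time": 1e-4,
             "triplet_fraction": -0.1},
        ],
    )
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            FcsModelParams(**kwargs)

    def test_monotone_decreasing_when_triplet_faster_than_diffusion(self):
        p = FcsModelParams(3.0, 5e-4, triplet_fraction=0.2,
                           triplet_lifetime=5e-6)
        c = analytic_acf(p, np.geomspace(1e-7, 1.0, 400))
        assert np.all(np.diff(c.g) < 0)


class TestFit:
    def test_noise_free_self_consistency(self):
        truth = FcsModelParams(5.0, 4e-4, aspect_ratio=5.75)
        curve = analytic_acf(truth, LAGS)
        res = fit_curve(
            curve,
            fixed=("aspect_ratio", "baseline", "triplet_fraction",
                   "triplet_lifetime"),
            init=FcsModelParams(2.0, 1e-4, aspect_ratio=5.75),
        )
        assert res.converged
        assert res.params.n_molecules == pytest.approx(5.0, rel=1e-6)
        assert res.params.diffusion_time == pytest.approx(4e-4, rel=1e-6)

    def test_round_trip_random_draws(self, rng):
        """Noise-free curves return their generating parameters (N, tau_D,
        T, tau_T free) to 1e-6 relative."""
        for _ in range(50):
            truth = FcsModelParams(
                n_molecules=float(rng.uniform(0.5, 100)),
                diffusion_time=float(rng.uniform(5e-5, 5e-3)),
                triplet_fraction=float(rng.uniform(0.05, 0.4)),
                triplet_lifetime=float(rng.uniform(1e-6, 2e-5)),
            )
            curve = analytic_acf(truth, np.geomspace(2e-7, 0.2, 200))
            res = fit_curve(curve, fixed=("aspect_ratio", "baseline"))
            assert res.converged
            assert res.params.n_molecules == pytest.approx(
                truth.n_molecules, rel=1e-6)
            assert res.params.diffusion_time == pytest.approx(
                truth.diffusion_time, rel=1e-6)
            assert res.params.triplet_fraction == pytest.approx(
                truth.triplet_fraction, rel=1e-5, abs=1e-7)
            assert res.params.triplet_lifetime == pytest.approx(
                truth.triplet_lifetime, rel=1e-5)

    def test_all_zero_curve_signals_amplitude_failure(self):
        curve = CorrelationCurve(LAGS, np.zeros_like(LAGS))
        res = fit_curve(curve, fixed=("aspect_ratio", "baseline",
                                      "triplet_fraction", "triplet_lifetime"))
        assert not res.converged
        assert "amplitude" in res.message

    def test_non_finite_curve_rejected(self):
        g = np.full_like(LAGS, 0.2)
        g[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_curve(CorrelationCurve(LAGS, g))

    def test_too_few_lags_rejected(self):
        curve = analytic_acf(FcsModelParams(5.0, 4e-4), LAGS[:3])
        with pytest.raises(ValueError, match="lags"):
            fit_curve(curve, fixed=("aspect_ratio", "baseline"))


class TestDerived:
    def test_diffusion_coefficient_reference_values(self):
        # omega = 0.25 um with tau_D = 441.4 us gives the cytosolic-eGFP
        # scale D = 35.4 um^2/s; 625 us gives 25.0
        assert diffusion_coefficient(0.25, 4.414e-4) == pytest.approx(
            35.4, abs=0.01)
        assert diffusion_coefficient(0.25, 6.25e-4) == pytest.approx(25.0)

    def test_diffusion_coefficient_domain(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(0.25, 0.0)
        with pytest.raises(ValueError):
            diffusion_coefficient(-0.25, 1e-4)

    def test_effective_volume_values(self):
        assert effective_volume(0.25, 5.747) == pytest.approx(0.500, abs=5e-4)
        assert effective_volume(1.0, 1.0) == pytest.approx(np.pi**1.5,
                                                           rel=1e-12)
        assert effective_volume(1.0, 1.0) == pytest.approx(5.568, abs=5e-4)

    def test_effective_volume_cubic_scaling(self):
        assert effective_volume(0.5, 4.0) == pytest.approx(
            8 * effective_volume(0.25, 4.0), rel=1e-12)

    def test_concentration_reference_values(self):
        # 1 molecule in 0.5 fl is 3.32 nM; linear in N; zero at N=0
        assert concentration(1.0, 0.5) * 1e9 == pytest.approx(3.32, abs=5e-3)
        assert concentration(10.0, 0.5) * 1e9 == pytest.approx(33.2, abs=5e-2)
        assert concentration(0.0, 0.5) == 0.0

    def test_concentration_halves_when_volume_doubles(self):
        assert concentration(5.0, 1.0) == pytest.approx(
            concentration(5.0, 0.5) / 2, rel=1e-12)

    def test_concentration_domain(self):
        with pytest.raises(ValueError):
            concentration(1.0, 0.0)
        with pytest.raises(ValueError):
            concentration(-1.0, 0.5)


class TestCalibration:
    def test_calibrate_from_noise_free_dye_curve(self):
        # dye with D = 400 um^2/s and tau_D = 39.06 us -> omega = 0.25 um,
        # V_eff = 0.5 fl at S = 5.747
        tau_d = 3.90625e-5
        truth = FcsModelParams(2.0, tau_d, aspect_ratio=5.747)
        curve = analytic_acf(truth, np.geomspace(1e-6, 1e-2, 100))
        cal = calibrate_volume(curve, dye_diff_coeff=400.0,
                               aspect_ratio=5.747)
        assert cal.lateral_radius == pytest.approx(0.25, rel=1e-6)
        assert cal.effective_volume_fl == pytest.approx(0.500, abs=5e-4)
        assert cal.dye_tau_d == pytest.approx(tau_d, rel=1e-6)

    def test_calibration_requires_positive_dye_d(self):
        curve = analytic_acf(FcsModelParams(2.0, 4e-5), LAGS)
        with pytest.raises(ValueError):
            calibrate_volume(curve, dye_diff_coeff=0.0)

    def test_derive_quantities_chain(self):
        cal = calibrate_volume(
            analytic_acf(FcsModelParams(2.0, 3.90625e-5, aspect_ratio=5.747),
                         np.geomspace(1e-6, 1e-2, 100)),
            dye_diff_coeff=400.0, aspect_ratio=5.747,
        )
        der = derive_quantities(FcsModelParams(3.0, 4.414e-4), cal)
        assert der.diffusion_coeff == pytest.approx(35.4, abs=0.05)
        assert der.concentration_nM == pytest.approx(3 * 3.32, rel=2e-3)
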