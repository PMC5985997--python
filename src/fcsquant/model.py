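"""Triplet-state one-component 3D diffusion model for FCS curves.

The observation volume of a confocal FCS instrument is well approximated by
a 3D Gaussian with lateral 1/e^2 radius omega and axial extent S*omega
(S is the aspect ratio).  For a single freely diffusing species with a
fraction T of fluorophores cycling through a dark triplet state of lifetime
tau_T, the normalized fluctuation autocorrelation is

    g(t) = baseline
           + (1/N) * (1 + T/(1-T) * exp(-t/tau_T))
                   * (1 + t/tau_D)^-1 * (1 + t/(S^2 tau_D))^-1/2

with N the mean number of molecules in the effective volume and tau_D the
diffusion (dwell) time.  The curves produced by :mod:`fcsquant.correlate`
decay to zero, so ``baseline`` defaults to 0; instruments that report
G -> 1 are accommodated by fitting or fixing ``baseline = 1``.

Derived quantities:

    D     = omega^2 / (4 tau_D)                    diffusion coefficient
    V_eff = pi^(3/2) * omega^3 * S                 effective volume
    C     = N / (V_eff * N_A)                      molar concentration

Volume calibration inverts the first relation on a reference dye of known
D to obtain omega (and hence V_eff) from a measured dye curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence

import lmfit
import numpy as np

from .correlate import CorrelationCurve

__all__ = [
    "AVOGADRO",
    "FcsModelParams",
    "FitResult",
    "VolumeCalibration",
    "DerivedQuantities",
    "analytic_acf",
    "acf_model",
    "fit_curve",
    "diffusion_coefficient",
    "effective_volume",
    "concentration",
    "calibrate_volume",
    "derive_quantities",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: default parameter bounds for fitting: (min, max)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "n_molecules": (1e-6, 1e4),
    "diffusion_time": (1e-6, 1.0),
    "triplet_fraction": (0.0, 0.5),
    "triplet_lifetime": (5e-7, 5e-5),
    "aspect_ratio": (1.0 + 1e-9, 100.0),
    "baseline": (-1.0, 2.0),
}

PARAM_NAMES = tuple(DEFAULT_BOUNDS)


@dataclass
class FcsModelParams:
    """Parameters of the triplet 3D-diffusion model.

    n_molecules : N, mean number of molecules in V_eff (dimensionless, > 0)
    diffusion_time : tau_D in seconds (> 0)
    triplet_fraction : T in [0, 1)
    triplet_lifetime : tau_T in seconds (> 0 whenever T > 0)
    aspect_ratio : S, axial/lateral extent of the volume (> 1)
    baseline : additive offset of the correlator convention (default 0)
    """

    n_molecules: float
    diffusion_time: float
    triplet_fraction: float = 0.0
    triplet_lifetime: float = 5e-6
    aspect_ratio: float = 5.747
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.n_molecules > 0):
            raise ValueError("n_molecules must be positive")
        if not (self.diffusion_time > 0):
            raise ValueError("diffusion_time must be positive")
        if not (0.0 <= self.triplet_fraction < 1.0):
            raise ValueError("triplet_fraction must be in [0, 1)")
        if self.triplet_fraction > 0 and not (self.triplet_lifetime > 0):
            raise ValueError("triplet_lifetime must be positive when T > 0")
        if not (self.aspect_ratio > 1):
            raise ValueError("aspect_ratio must exceed 1")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}


def acf_model(
    t: np.ndarray,
    n_molecules: float,
    diffusion_time: float,
    triplet_fraction: float = 0.0,
    triplet_lifetime: float = 5e-6,
    aspect_ratio: float = 5.747,
    baseline: float = 0.0,
) -> np.ndarray:
    """Model g(t) evaluated on an array of lag times (vectorized, unchecked)."""
    t = np.asarray(t, dtype=float)
    diff = (1.0 + t / diffusion_time) ** -1.0
    diff = diff * (1.0 + t / (aspect_ratio**2 * diffusion_time)) ** -0.5
    if triplet_fraction > 0:
        trip = 1.0 + triplet_fraction / (1.0 - triplet_fraction) * np.exp(
            -t / triplet_lifetime
        )
    else:
        trip = 1.0
    return baseline + trip * diff / n_molecules


def analytic_acf(params: FcsModelParams, lags: Sequence[float]) -> CorrelationCurve:
    """Evaluate the model on a lag grid (lag 0 permitted).

    The closed form serves both as the fit model and as the independent
    oracle for the Brownian-dynamics simulator.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size and lags.min() < 0:
        raise ValueError("lags must be non-negative")
    g = acf_model(lags, **params.as_dict())
    return CorrelationCurve(lags, g, source={"estimator": "analytic",
                                             "params": params.as_dict()})


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit of the model to a curve."""

    params: FcsModelParams
    stderrs: dict[str, float]
    residuals: np.ndarray
    chi_square: float
    reduced_chi_square: float
    converged: bool
    fixed_params: tuple[str, ...]
    message: str = ""
    lags: np.ndarray = field(default_factory=lambda: np.empty(0))

    def model_curve(self) -> CorrelationCurve:
        return analytic_acf(self.params, self.lags)


def _initial_guess(curve: CorrelationCurve, fixed: Sequence[str],
                   init: Optional[FcsModelParams]) -> FcsModelParams:
    if init is not None:
        return init
    g0 = float(curve.g[0])
    if not np.isfinite(g0) or g0 <= 0:
        raise ValueError("non-positive amplitude at the smallest lag")
    n0 = 1.0 / g0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau0 = float(curve.lags[below[0]]) if below.size else float(curve.lags[-1])
    tau0 = min(max(tau0, DEFAULT_BOUNDS["diffusion_time"][0] * 1.01),
               DEFAULT_BOUNDS["diffusion_time"][1] * 0.99)
    t0 = 0.0 if "triplet_fraction" in fixed else 0.15
    return FcsModelParams(
        n_molecules=min(max(n0, 1e-3), 1e4),
        diffusion_time=tau0,
        triplet_fraction=t0,
        triplet_lifetime=5e-6,
    )


def fit_curve(
    curve: CorrelationCurve,
    init: Optional[FcsModelParams] = None,
    fixed: Sequence[str] = ("aspect_ratio", "baseline"),
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    *,
    lag_range: Optional[tuple[float, float]] = None,
    weighted: bool = True,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the triplet diffusion model.

    Parameters
    ----------
    curve : CorrelationCurve
        Measured curve.  When ``curve.g_err`` is present and ``weighted``,
        residuals are weighted by 1/g_err (zero/non-finite errors fall back
        to the median error).
    init : FcsModelParams, optional
        Starting values; by default N0 = 1/g(first lag), tau_D0 = lag at
        half amplitude, T0 = 0.15, tau_T0 = 5 us.
    fixed : sequence of str
        Parameter names held at their initial value.  The aspect ratio is
        fixed by default (it comes from the volume calibration, not from
        cellular curves); pass ``fixed=()`` to free everything.
    bounds : dict, optional
        Per-parameter (min, max) overriding the defaults.
    lag_range : (float, float), optional
        Fit only lags within this window (seconds).
    """
    lags = np.asarray(curve.lags, dtype=float)
    g = np.asarray(curve.g, dtype=float)
    if not (np.all(np.isfinite(lags)) and np.all(np.isfinite(g))):
        raise ValueError("curve contains non-finite values")
    g_err = curve.g_err
    if lag_range is not None:
        m = (lags >= lag_range[0]) & (lags <= lag_range[1])
        lags, g = lags[m], g[m]
        g_err = None if g_err is None else g_err[m]
    if lags.size == 0:
        raise ValueError("no lags left to fit")
    fixed = tuple(fixed)

    n_free = len([p for p in PARAM_NAMES if p not in fixed])
    if lags.size < 2 * n_free:
        raise ValueError(
            f"curve has {lags.size} lags; need at least {2 * n_free} "
            f"for {n_free} free parameters"
        )

    def _failure(msg: str, init_params: Optional[FcsModelParams]) -> FitResult:
        p = init_params or FcsModelParams(1.0, 1e-4)
        return FitResult(
            params=p, stderrs={}, residuals=np.full_like(g, np.nan),
            chi_square=float("nan"), reduced_chi_square=float("nan"),
            converged=False, fixed_params=fixed, message=msg, lags=lags,
        )

    try:
        start = _initial_guess(
            CorrelationCurve(lags, g), fixed, init
        )
    except ValueError as exc:
        return _failure(str(exc), init)

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    pars = lmfit.Parameters()
    for name in PARAM_NAMES:
        val = float(getattr(start, name))
        lo, hi = bnds[name]
        if name in fixed:
            pars.add(name, value=val, vary=False)
        else:
            val = min(max(val, lo), hi)
            pars.add(name, value=val, min=lo, max=hi)

    weights = None
    if weighted and g_err is not None:
        err = np.asarray(g_err, dtype=float).copy()
        bad = ~np.isfinite(err) | (err <= 0)
        if bad.all():
            err = None
        else:
            med = np.median(err[~bad])
            err[bad] = med if med > 0 else 1.0
        if err is not None:
            weights = 1.0 / err

    def residual(p: lmfit.Parameters) -> np.ndarray:
        r = acf_model(lags, **{k: p[k].value for k in PARAM_NAMES}) - g
        return r * weights if weights is not None else r

    try:
        out = lmfit.minimize(residual, pars, method="least_squares",
                             ftol=1e-12, xtol=1e-12, gtol=1e-12)
    except Exception as exc:  # lmfit raises on pathological inputs
        return _failure(f"fit failed: {exc}", init)

    values = {k: float(out.params[k].value) for k in PARAM_NAMES}
    try:
        fitted = FcsModelParams(**values)
    except ValueError as exc:
        return _failure(f"fit left invalid parameters: {exc}", init)

    stderrs = {
        k: float(out.params[k].stderr)
        for k in PARAM_NAMES
        if k not in fixed and out.params[k].stderr is not None
    }
    resid = acf_model(lags, **values) - g
    chisq = float(np.sum(residual(out.params) ** 2))
    nfree = max(lags.size - n_free, 1)
    return FitResult(
        params=fitted,
        stderrs=stderrs,
        residuals=resid,
        chi_square=chisq,
        reduced_chi_square=chisq / nfree,
        converged=bool(out.success),
        fixed_params=fixed,
        message=str(getattr(out, "message", "")),
        lags=lags,
    )


# ---------------------------------------------------------------------------
# derived quantities


def diffusion_coefficient(lateral_radius: float, diffusion_time: float) -> float:
    """D = omega^2 / (4 tau_D), in um^2/s for omega in um and tau_D in s."""
    if not (lateral_radius > 0):
        raise ValueError("lateral_radius must be positive")
    if not (diffusion_time > 0):
        raise ValueError("diffusion_time must be positive")
    return lateral_radius**2 / (4.0 * diffusion_time)


def effective_volume(lateral_radius: float, aspect_ratio: float) -> float:
    """V_eff = pi^(3/2) omega^3 S of the 3D Gaussian volume, in fl.

    1 um^3 = 1 fl, so with omega in um the result is directly femtoliters.
    """
    if not (lateral_radius > 0 and aspect_ratio > 0):
        raise ValueError("lateral_radius and aspect_ratio must be positive")
    return math.pi**1.5 * lateral_radius**3 * aspect_ratio


def concentration(n_molecules: float, effective_volume_fl: float) -> float:
    """C = N / (V_eff * N_A) in mol/L, with V_eff given in fl."""
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    if not (effective_volume_fl > 0):
        raise ValueError("effective_volume must be positive")
    return n_molecules / (effective_volume_fl * 1e-15 * AVOGADRO)


@dataclass
class DerivedQuantities:
    """Diffusion coefficient and molar concentration derived from a fit."""

    diffusion_coeff: float  # um^2/s
    concentration_molar: float  # mol/L

    @property
    def concentration_nM(self) -> float:
        return self.concentration_molar * 1e9


@dataclass
class VolumeCalibration:
    """Observation-volume geometry from a reference-dye measurement."""

    lateral_radius: float  # um
    aspect_ratio: float
    effective_volume_fl: float
    dye_diff_coeff: float  # um^2/s, literature value supplied as input
    dye_tau_d: float  # s, fitted

    def __post_init__(self) -> None:
        if not (self.lateral_radius > 0 and self.aspect_ratio > 0):
            raise ValueError("calibration geometry must be positive")
        expected = effective_volume(self.lateral_radius, self.aspect_ratio)
        if not math.isclose(self.effective_volume_fl, expected, rel_tol=1e-12):
            raise ValueError("effective_volume inconsistent with omega and S")


def calibrate_volume(
    dye_curve: CorrelationCurve,
    dye_diff_coeff: float,
    aspect_ratio: float = 5.747,
    *,
    fit_triplet: bool = False,
    lag_range: Optional[tuple[float, float]] = None,
    baseline: float = 0.0,
) -> VolumeCalibration:
    """Calibrate omega and V_eff from a reference-dye correlation curve.

    The dye's literature diffusion coefficient (um^2/s) is a required
    input; the fitted dwell time tau_D then gives
    omega = sqrt(4 D_dye tau_D).
    """
    if not (dye_diff_coeff > 0):
        raise ValueError("dye_diff_coeff must be positive")
    fixed = ["aspect_ratio", "baseline"]
    if not fit_triplet:
        fixed += ["triplet_fraction", "triplet_lifetime"]
    init = FcsModelParams(
        n_molecules=1.0, diffusion_time=1e-4,
        triplet_fraction=0.15 if fit_triplet else 0.0,
        aspect_ratio=aspect_ratio,
        baseline=baseline,
    )
    # seed N/tau_D from the curve itself, keep S and triplet policy
    guess = _initial_guess(dye_curve, fixed, None)
    init = replace(init, n_molecules=guess.n_molecules,
                   diffusion_time=guess.diffusion_time)
    res = fit_curve(dye_curve, init=init, fixed=fixed, lag_range=lag_range)
    if not res.converged:
        raise RuntimeError(f"dye-curve fit did not converge: {res.message}")
    tau_d = res.params.diffusion_time
    if not (tau_d > 0):
        raise RuntimeError("fitted diffusion time is non-positive")
    omega = math.sqrt(4.0 * dye_diff_coeff * tau_d)
    return VolumeCalibration(
        lateral_radius=omega,
        aspect_ratio=aspect_ratio,
        effective_volume_fl=effective_volume(omega, aspect_ratio),
        dye_diff_coeff=dye_diff_coeff,
        dye_tau_d=tau_d,
    )


def derive_quantities(
    fit: FitResult | FcsModelParams, calibration: VolumeCalibration
) -> DerivedQuantities:
    """Convert a fitted (N, tau_D) into D (um^2/s) and C (mol/L)."""
    params = fit.params if isinstance(fit, FitResult) else fit
    d = diffusion_coefficient(calibration.lateral_radius, params.diffusion_time)
    c = concentration(params.n_molecules, calibration.effective_volume_fl)
    return DerivedQuantities(diffusion_coeff=d, concentration_molar=c)
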