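# fcsquant

Quantitative fluorescence correlation spectroscopy (FCS), from photon
traces to diffusion coefficients and molar concentrations — plus the
image-based promoter-strength quantification that goes with it.

## The problem

Single-molecule techniques such as FCS only work when few fluorescent
molecules occupy the confocal observation volume at a time (roughly 5–20
molecules in ~0.5 fl, i.e. tens of nanomolar). Choosing expression
constructs that hit this window — e.g. weak herpes-simplex thymidine
kinase promoter variants instead of the very strong CMV/SV40 promoters —
requires two quantitative pipelines:

1. **FCS**: record 20-s fluorescence fluctuation traces as labeled
   proteins (e.g. eGFP) diffuse through the volume, autocorrelate them,
   fit a diffusion model, and convert the fit into a diffusion
   coefficient and an absolute concentration;
2. **Imaging**: rank construct strength by background-corrected per-cell
   mean fluorescence, normalized to a reference construct.

`fcsquant` implements both ends to end, together with a
Brownian-dynamics simulator that generates photon traces and synthetic
cell images with known ground truth, so every stage is testable without
instrument data.

## The model

The observation volume is a 3D Gaussian with lateral radius ω and aspect
ratio S (axial extent Sω), effective volume V_eff = π^{3/2} ω³ S. The
fluctuation autocorrelation G(τ) = ⟨δF(t)·δF(t+τ)⟩ / ⟨F⟩² of a single
diffusing species with triplet blinking is fitted with

    g(τ) = (1/N) · (1 + T/(1−T) · e^{−τ/τ_T})
                 · (1 + τ/τ_D)^{−1} · (1 + τ/(S² τ_D))^{−1/2}

where N is the mean molecule number in V_eff, τ_D the diffusion (dwell)
time, and T, τ_T the triplet fraction and lifetime. Derived quantities:

    D = ω² / (4 τ_D)          C = N / (V_eff · N_A)

ω comes from a calibration measurement of a reference dye of known D.

## Worked example

Simulate one 20-s acquisition of cytosolic eGFP (5 molecules in the
calibrated 0.25-µm / 0.5-fl volume, D = 35.4 µm²/s, 15 % triplet) and
push it through the full analysis:

```python
from fcsquant import (TraceSimConfig, simulate_diffusion_trace, analyze_trace,
                      VolumeCalibration, effective_volume)

cal = VolumeCalibration(0.25, 5.747, effective_volume(0.25, 5.747),
                        dye_diff_coeff=400.0, dye_tau_d=3.906e-5)

cfg = TraceSimConfig(mean_occupancy=5.0, diff_coeff=35.4,
                     duration=20.0, bin_width=2e-5, time_step=2e-5, seed=2)
trace = simulate_diffusion_trace(cfg)
print(f"mean count rate: {trace.mean_rate():.0f} photons/s")

a = analyze_trace(trace, cal, closed_box_molecules=cfg.n_molecules)
print(f"QC accepted: {a.qc.accepted}")
p = a.fit.params
print(f"N = {p.n_molecules:.2f} molecules, tau_D = {p.diffusion_time*1e6:.0f} us")
print(f"D = {a.derived.diffusion_coeff:.1f} um^2/s, "
      f"C = {a.derived.concentration_nM:.1f} nM")
print(f"suitability: {a.suitability.verdict}")
```

prints

```
mean count rate: 7427 photons/s
QC accepted: True
N = 5.12 molecules, tau_D = 429 us
D = 36.4 um^2/s, C = 17.0 nM
suitability: optimal
```

The trace passed the stationarity screen; the fit recovered ~5 molecules
(17 nM in 0.5 fl) with a dwell time of ~430 µs, i.e. D ≈ 36 µm²/s for
the programmed 35.4 — and the expression level is flagged as inside the
optimal 5–20-molecule FCS window. A single 20-s run carries a few
percent of statistical scatter in N and ~10 % in D; condition-level
numbers average ≥ 25 runs (`fcsquant.protocols`).

The same library drives a CLI (`fcsquant simulate-trace | correlate |
screen | calibrate | fit | simulate-image | quantify | report`) with
text/CSV/JSON/TIFF artifacts throughout.

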