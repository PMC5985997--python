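# Methods

## Scope

`fcsquant` implements the quantitative chain behind confocal fluorescence
correlation spectroscopy (FCS) of fluorescent-protein expression
constructs: a Brownian-dynamics photon-trace simulator, the fluctuation
autocorrelation estimator, the triplet one-component 3D diffusion model
with observation-volume calibration, trace quality screening, and the
background-subtracted per-cell intensity quantification used to rank
promoter strength. Everything downstream of the simulator is the same
code a user would point at measured traces, curves or micrographs.

## Physical model

The observation volume is a 3D Gaussian molecular detection function
(MDF)

    W(x, y, z) = exp(-2 (x^2 + y^2) / omega^2 - 2 z^2 / (S omega)^2)

with lateral 1/e^2 radius `omega` (um) and aspect ratio `S` (axial
extent `S*omega`). Its effective volume is V_eff = pi^(3/2) omega^3 S;
with the calibrated omega = 0.25 um and S = 5.747 this is 0.50 fl, the
standard confocal scale. For a single freely diffusing species with a
dark triplet fraction `T` of lifetime `tau_T`, the normalized
fluctuation autocorrelation is

    g(t) = baseline + (1/N) (1 + T/(1-T) e^(-t/tau_T))
                      (1 + t/tau_D)^(-1) (1 + t/(S^2 tau_D))^(-1/2)

with `N` the mean molecule number in V_eff and `tau_D` the dwell time.
The `baseline` parameter absorbs the known additive offset of the
measured curve: 0 for an ideal open system, 1 for hardware correlators
that report G -> 1, and a small negative constant for curves measured on
a closed system of fixed molecule count (see *Fitting and calibration*).
Derived quantities: D = omega^2/(4 tau_D) and C = N/(V_eff N_A).

With N defined against V_eff = pi^(3/2) omega^2 z0 (rather than the bare
integral of W), the amplitude of the simulated correlation is exactly
1/N — no separate gamma factor appears.

## Simulator

Point emitters diffuse in a periodic box whose half-widths default to
5 (omega, omega, S omega) per axis, i.e. a box of 1000/pi^(3/2) ~ 180
effective volumes; the box molecule count is
`round(occupancy * V_box / V_eff)`. Photons arrive as a Poisson process
of rate `brightness * W(position) * B(t)` plus a uniform background,
integrated per bin; `B(t)` is the two-state triplet telegraph
(bright -> dark at T/tau_T, dark -> bright at (1-T)/tau_T; stationary
dark fraction T, relaxation time tau_T).

Numerical choices:

- **Brownian increments are exact at any step size** (Gaussian with
  per-axis variance 2 D dt), so the time step only controls the
  quadrature of W along the path within a bin. The default step is
  min(bin width, tau_D/20); fits exclude the first two lags, where the
  held-value quadrature smears the curve. At one step per bin the
  sampled-process autocorrelation at lags >= 1 bin is exactly the
  continuous-time correlation function, because the per-bin rate equals
  a single W sample.
- **Blinking is simulated exactly in continuous time**, not as a
  per-step Markov chain: inside emitting steps the telegraph is advanced
  with exponential holding times (the bright-time integral of each step
  is exact), and across intervals spent far from the focus the state is
  propagated with the closed-form two-state propagator
  P(bright | state) = (1-T) + (1{bright} - (1-T)) e^(-gap/tau_T).
  This removes any constraint tying the time step to tau_T, which is
  what makes the mandated 20-s, ~900-molecule acquisitions computable;
  a discrete chain with p = k dt would need dt << tau_T = 5 us and
  ~40x more work for less accuracy.
- **Far-field tiering.** Molecules whose MDF exponent (after deflating
  each coordinate by three standard deviations of the candidate jump)
  exceeds 26 — where W < 5.1e-12 — take 4x or 16x longer steps and emit
  nothing. The missed-contribution bound is ~1e-4 of the mean rate,
  far below shot noise. This is a quadrature optimization, not a model
  change; it cuts runtime roughly threefold.
- Per-bin counts are Poisson draws on the accumulated rate; all
  randomness flows through one `numpy` Generator, so a (config, seed)
  pair reproduces traces bit for bit.

Default study conditions mirror a cytosolic eGFP measurement: occupancy
5 in the 0.5-fl volume, D = 35.4 um^2/s (tau_D ~ 441 us), triplet
T = 0.15 with tau_T = 5 us, 20-s acquisitions, detected brightness
5e3 photons/s per molecule at the volume center (a realistic in-cell
count rate at ~1 uW excitation; reference-dye protocols use 3e4, as
organic dyes in solution are several-fold brighter). Protocol runs bin
cell traces at 20 us and dye traces at 4 us — well below the respective
diffusion times of ~441 us and ~39 us — which keeps a 25-trace condition
within minutes on one core; because the sampled-process correlation is
exact at one step per bin (above), the analysis is bin-width-agnostic
above the first two lags.

## Correlator

`autocorrelate_direct` is the literal estimator
G_k = mean_t dF(t) dF(t+k) / <F>^2 on a linear lag grid (truncated
products; a circular variant exists for periodic test fixtures).
`autocorrelate_multitau` reproduces the quasi-logarithmic grid of
hardware correlators: `m` linear lags per octave with pairwise rebinning
between octaves, so a 10^6-bin trace correlates over five decades of lag
in O(m n). Within the first octave no rebinning occurs and the two
estimators agree to floating precision. Per-lag standard errors come
from splitting the trace into contiguous blocks (10 by default) and
taking the standard error of the block estimates.

Two finite-trace properties worth knowing:

- normalizing by the estimated mean biases every lag down by
  O(sum_j G(j)/n); ~2% of the amplitude on a 1-s trace at these
  conditions and ~0.1% on the protocol's 20-s traces;
- octave rebinning averages the true curve over a triangular kernel one
  level wide, a sub-percent smoothing at the default eight points per
  octave.

## Fitting and calibration

`fit_curve` is a bounded nonlinear least-squares fit (via lmfit /
trust-region reflective) of the model above, weighted by 1/g_err^2 when
block errors are present. Initial guesses: N0 = 1/g(first lag), tau_D0 =
lag at half amplitude, T0 = 0.15, tau_T0 = 5 us; bounds N in (0, 1e4],
tau_D in [1 us, 1 s], T in [0, 0.5], tau_T in [0.5, 50] us. The aspect
ratio is fixed by default — geometry belongs to the dye calibration, not
to cell curves — and the default pipeline windows fits to
[max(3 tau_T, 2 bins), duration/10]: the head is dominated by triplet
blinking (and on hardware by detector afterpulsing), the tail by
estimator variance. On windows past the triplet decay, T is fixed at 0;
the residual triplet contribution at 3 tau_T is below 1% of the
amplitude. A non-positive amplitude or an optimizer failure is reported
as `converged=False` with a reason, never silently.

When no explicit lag window is given the fit is two-pass: a first pass
estimates tau_D over the default window, and the final fit re-windows to
min(max(16 tau_D, 32 bins), duration/10), where the free-diffusion model
carries the decay information and long-lag estimator artifacts (finite
box, block-noise) cannot leak in.

**Closed-system baseline.** A closed box of exactly M molecules has no
number fluctuations at the whole-box scale, so its fluctuation
correlation decays to -1/M rather than 0; normalizing by the trace's own
empirical mean subtracts a further ~2 integral(G)/duration. Both offsets
are known constants of the acquisition — `known_curve_offset` computes
them from M, the measured curve and the duration — and the pipeline
fixes the model baseline there rather than fitting it (a free baseline
is nearly degenerate with tau_D over any practical fit window). The
effect is small (~0.6% of the amplitude at the default box) but, left
uncorrected, its relative weight grows as 1/g(t) along the decay and
biases tau_D low by a few percent.

`calibrate_volume` fits a reference-dye curve (T = 0), converts the
dwell time through the dye's literature D — a required input, since
calibration dyes differ — to omega = sqrt(4 D tau_D), and V_eff through
the 3D-Gaussian closed form. Cell-trace fits then reuse (omega, S)
fixed.

## Quality screening

Confined, colliding or membrane-bound molecules show slow drifts or
oscillations of the count rate; such traces must be removed before
correlation. Two statistics on segment means of the counts-per-bin
signal:

- **drift**: over 10 equal segments, (max - min)/mean, threshold 0.2;
- **oscillation**: over 50 segments, Var(segment means) divided by its
  expectation for a *stationary* trace, threshold 3.

The stationary expectation is estimated within the trace itself: each
segment is split into 10 sub-segments and the scaled variance of
sub-segment means is pooled, floored at the Poisson value mean/L. The
nested denominator matters: a healthy FCS trace is not shot-noise
limited at low frequency — molecular number fluctuations carry excess
power ~ 2 g(0) tau_corr rate above the shot floor (a factor of several
at the default conditions) — so a shot-noise-normalized score would
reject stationary single-molecule traces wholesale. Fluctuations much
faster than a segment cancel in the ratio; drifts and modulations slower
than a few segments inflate only the numerator. The thresholds are
calibrated to the 20-s protocol: segment-mean scatter scales as
sqrt(tau_corr/duration), so much shorter traces need proportionally
relaxed drift thresholds.

Suitability: expression levels with a fitted N in [5, 20] are flagged
optimal for FCS; below, the signal is too dim; above (strong-promoter
overexpression), relative fluctuations drown in detector noise.

## Image arm

`simulate_cell_image` renders non-overlapping elliptical cells with
uniform cytosolic plateaus on a uniform background with Gaussian read
noise, 16-bit quantization, and optional small bright foci that belong
to the cell (included in whole-cell quantification, flagged in a
separate mask so FCS positioning can avoid them). Per-cell plateaus are
explicit or drawn from a per-construct log-normal law, emulating
transient-transfection variability. The ground-truth table carries the
exact foci-inclusive expected in-mask mean.

Quantification mirrors the ImageJ workflow: background subtraction
(supplied value or mean of a non-cell region, clipped at zero),
whole-cell mean over each mask, saturation flag when >= 1% of raw mask
pixels sit at the bit-depth maximum, per-construct mean +/- SD over at
least 10 cells, and rescaling so a designated reference construct reads
10. Constructs dominated by saturated cells are excluded from the
normalized comparison as out of range. Construct contrasts use Welch's
unequal-variance t-test on per-cell means (the ratio of means is the
effect size); with zero variance in both groups only the ratio is
reported.

What the synthetic images do **not** emulate: real cell morphology,
intracellular texture, illumination shading, or segmentation errors
(masks are inputs by design). Passing the ratio-recovery tests therefore
validates the measurement arithmetic, not a segmentation algorithm.

## Reference protocols and problem sizes

`fcsquant.protocols` packages the two standard study conditions — the
cellular eGFP protocol (25 x 20-s traces at 20-us bins, screened, T
fixed at 0 past the triplet window) and the dye calibration (24 x 2-s
bright traces at 4-us bins, ensemble-averaged curve with pooled block
errors, single two-pass fit) — plus an occupancy-recovery sweep (1, 5,
20 molecules, 20 x 3-s traces each at 40-us bins). All seeds derive
from one integer via `SeedSequence`. These sizes reproduce the
reference values (mean recovered D within ~1 um^2/s of 35.4, omega
within ~2%, V_eff within ~5%) in minutes of single-core time; longer
traces or more repeats shrink the seed-to-seed scatter as 1/sqrt(n) but
change nothing structurally.

The occupancy sweep reports the FCS-suitability verdict of each
condition's mean fitted N. Band classification at the edges respects
the estimate's precision: a mean within two standard errors of a band
boundary is classified as sitting on the boundary (which the inclusive
[5, 20] band counts as optimal). Without this convention, a condition
whose true N equals an edge — occupancy 5 does — would be classified by
the sign of a vanishing estimation error.

## Known limitations

- One diffusing species, one triplet state: no photobleaching kinetics,
  no FRET, no anomalous diffusion, no two-color cross-correlation.
- The periodic box reuses molecules; correlations at lags approaching
  the box-crossing time (L^2/2D, ~10 ms laterally for the dye) acquire a
  small re-entry excess, which the default fit windows avoid.
- The empirical-mean normalization bias above is inherent to
  finite-trace estimators and is left uncorrected, matching standard
  practice; it is negligible at protocol durations.
- The screen statistics are rate-based; pathologies that preserve the
  count-rate distribution while reordering time (e.g. subtle flow) are
  not targeted.
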