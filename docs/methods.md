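# Methods

## Model

A spindle is modeled as `s(t) = exp(A(t)) cos(P(t))` with quadratic
instantaneous log-amplitude `A(t) = a + b t + c t²` and phase
`P(t) = d + e t + f t²`. This is the minimal polynomial order that lets both
the envelope and the instantaneous frequency `(e + 2 f t)/2π` vary within
the analysis window: spindles wax and wane (c < 0 gives the Gaussian-like
envelope; b skews it) and drift in frequency (f). The quadratic expansion is
taken about the window center, so all parameters are local to `t = 0` at the
segment midpoint; segment extraction from recordings centers each window on
the annotation midpoint and stores the recording-time center separately
(`t_c`) purely as bookkeeping. Because the model is even in
`(d, e, f) → (−d, −e, −f)` and 2π-periodic in `d`, parameter sets are only
identifiable up to those symmetries; the canonical representative
(`e > 0`, `d ∈ (−π, π]`) is produced by `canonicalize_params` and reported
by the fitter, while the optimizer itself works unwrapped (d is bounded at
±4π so the iterates never wrap mid-descent).

The default analysis window is 1 s at 256 Hz (n = 256, giving v = 250
residual degrees of freedom with m = 6 coefficients), the native sampling
rate of standard PSG archives; fitting on the annotated spindle extent
instead is available via `window_mode="annotation_span"`.

## Estimation

`fit_qps` minimizes the residual sum of squares with
`scipy.optimize.least_squares` and an analytic Jacobian. Called without
bounds it is classic Levenberg–Marquardt. The default, though, applies box
constraints loosely encoding the clinical spindle definition — frequency
8–20 Hz (wider than the 11–16 Hz sigma band so the optimizer can move),
decaying envelopes `c ∈ [−200, −10⁻³] 1/s²`, `a ∈ [−5, 10]`,
`b ∈ [−20, 20] 1/s`, `d ∈ [−4π, 4π]`, `f ∈ [−60, 60] rad/s²` — and then a
trust-region reflective variant runs, which coincides with LM on interior
solutions. The result records which path ran. Convergence tolerances
(step, gradient, cost) are 1e−10 with at most 2000 model evaluations; there
is no randomness inside the fitter.

Starting values: the `spindle_like` mode uses the data peak for amplitude
(`a = ln max|s|`), a symmetric moderately decaying envelope (b = 0,
c = −20 1/s²) and a mid-band 13 Hz carrier (d = 0, f = 0). The `zeros` mode
(all six zero, projected onto the bounds when bounds are active) is the
neutral start appropriate for non-spindle segments, where assuming a
spindle-like waveform would bias the comparison. NLLS from a fixed start
can land in a local minimum when the data's true carrier is far from
13 Hz; when a fit explains less than 80% of the variance, one deterministic
restart is taken with the carrier read off the dominant spectral peak and
the lower-SSE solution kept (`fallback_used` flags it). On the
spindle-range parameter box this leaves noiseless round-trip recovery
exact to < 1e−3 relative error.

95% confidence bounds use the standard NLLS construction
`cov = (JᵀJ)⁻¹ · SSE/v` with a Student-t quantile at v degrees of freedom;
a singular Jacobian flags the intervals unavailable rather than failing the
fit.

Goodness of fit follows the usual regression bookkeeping: SSE,
`R² = 1 − SSE/SST`, `adjR² = 1 − SSE(n−1)/(SST·v)`, `RMSE = √(SSE/v)`. A
constant observed signal leaves R² undefined (NaN, flagged) rather than
raising.

## Signal-side reference quantities

Fits on real data are validated through two quantities computable both from
the parameters and from the raw segment. Energy is the area under the
amplitude envelope: model-side the Gaussian integral of
`exp(a + b t + c t²)` in closed erf form (adaptive quadrature only in the
degenerate `c ≈ 0` case, where the closed form divides by ~0); signal-side
the trapezoidal area under the analytic-signal (Hilbert) envelope.
Frequency is `e/2π` model-side and the dominant peak of the zero-padded
(≥ 4096-point) magnitude spectrum signal-side, searched in a 9–18 Hz band
(the sigma band with margin, configurable), ties broken toward the lower
frequency.

## Synthetic data

The generators emulate the study conditions without shipping clinical data:

- **White noise at stated SNR** — zero-mean Gaussian with variance
  `P_signal / 10^(SNR/10)`; the realized SNR is recorded in segment
  metadata.
- **Delta-band background** — Gaussian noise band-passed to 0.5–4 Hz with a
  zero-phase 4th-order Butterworth (generated with 2 s padding each side so
  no filter transient enters the segment), scaled to a requested RMS. This
  is a *surrogate* for raw EEG segments with strong slow-wave activity: it
  reproduces their spectral location and stationarity on the 1 s scale but
  none of real EEG's nonstationarity, non-Gaussianity, or in-band (sigma)
  power. Parameter-recovery numbers under this surrogate are therefore
  optimistic relative to real recordings, and the robustness experiment
  should be read as "the estimator is unbiased under strong out-of-band
  interference", not as a real-EEG error bar.
- **Mixing protocol** — `spindle + gain × background` with gain 2 by
  default; the background RMS defaults to the clean spindle's RMS, so
  gain 2 puts 4× the spindle's power in the background. The absolute
  amplitude relationship between background and spindle is a configuration
  knob (`background_rms`), not a constant, since only the amplification
  factor of the protocol is fixed.
- **Non-spindle surrogate** — one-second 1/f ("pink") noise segments,
  mimicking unmarked broadband EEG.

All generators are pure functions of (spec, seed); experiment-level seeds
are split into per-trial child seeds with `numpy.random.default_rng`
seed sequences, so every experiment is bitwise reproducible from one
integer.

## Experiments

- `snr_sweep` scores each fit against the **noise-free** reference
  waveform, so R² → 1 exactly in the high-SNR limit; medians over 20 trials
  per SNR are reported. Default grid {0, 5, 10, 20, 40} dB.
- `background_robustness` refits the same spindle under 190 independent
  delta surrogates (the study's segment count) and summarizes each
  parameter's estimate distribution with mean/min/max and both whisker
  conventions — ±2.7σ and the 1.5·IQR boxplot rule it approximates — since
  the two only coincide for normal data.
- `compare_groups` implements the spindle vs non-spindle comparison. A
  "two-sided non-parametric t-test" is self-contradictory, so both Welch's
  t (default) and Mann–Whitney U are available and the result records which
  ran, along with each group's init protocol (same-init vs different-init
  designs give different answers, and that dependence is part of the
  finding). Significance level defaults to 1%.
- `summarize_parameters` gives per-group means/variances with ±2σ and
  ±2.7σ ranges, or an ordered time series for overnight tracking; groups
  with one fit get NaN variance, flagged rather than fabricated.
- `shape_sweep` regenerates waveforms while varying one parameter and
  summarizes peak-to-peak, envelope peak time, envelope FWHM and dominant
  frequency — the visual-interpretation aid for each parameter's role.

## Problem sizes

The packaged experiments run at desk scale by design: 100 noise
realizations for the headline medians, 20 trials per SNR cell, 190
background trials, 30-spindle synthetic cohorts, 1000 replicates for the
type-I-error calibration of the group test. These sizes put Monte-Carlo
error well below the tolerances asserted in the tests while keeping the
whole suite in seconds.

## Known limitations

- No spindle *detector* is included: the model quantifies already-marked
  segments. Detection would require a prior estimation stage or an
  initial-condition-free estimator, since NLLS outcomes on non-spindle data
  depend strongly on the start values.
- Real-EEG accuracy figures (scorer-dependent energy/frequency errors,
  parameter variances across participants) depend on the recording archive
  and its expert annotations and are not reproduced by the synthetic
  surrogates; the I/O layer (EDF + annotation CSV) exists so users can run
  those analyses on data they hold.
- The EDF writer is a minimal 16-bit encoder for generating synthetic test
  fixtures, not a clinical-grade exporter.
- Cubic-and-higher polynomial amplitude/phase models are out of scope.
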