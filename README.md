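# qpspindle

Parametric modeling of EEG sleep spindles with a quadratic-parameter
sinusoid (QPS), for sleep researchers and signal-processing practitioners
who need more than a band-power number per spindle: a six-parameter
description of each burst's amplitude, envelope shape, phase and
within-spindle frequency drift.

## The model

Sleep spindles — 11–16 Hz oscillatory EEG bursts of 0.5–2 s with a waxing
and waning envelope — are non-stationary: their instantaneous amplitude and
frequency evolve within the burst. The QPS captures this with quadratic
log-amplitude and phase:

```
s(t) = exp(a + b t + c t²) · cos(d + e t + f t²)
```

with `t` in seconds and `t = 0` at the analysis-window center:

| param | meaning | units |
|-------|---------|-------|
| `a` | log-amplitude at the window center | log signal units |
| `b` | log-amplitude rate (envelope skew) | 1/s |
| `c` | Gaussian envelope curvature (c < 0 decays) | 1/s² |
| `d` | initial phase | rad |
| `e` | angular frequency at center; carrier = e/2π Hz | rad/s |
| `f` | frequency sweep rate; inst. frequency = (e + 2 f t)/2π | rad/s² |

Parameters are estimated by nonlinear least squares (Levenberg–Marquardt,
or a bounded trust-region variant when the default sigma-band constraints
are active), with 95% confidence bounds from the Jacobian, and four
goodness-of-fit measures: SSE, R², degrees-of-freedom–adjusted R² and
RMSE (v = n − 6 residual degrees of freedom).

The package also ships the validation experiments as seeded, reproducible
functions: white-noise SNR sweeps, delta-band (0.5–4 Hz) background
robustness, envelope-area energy and dominant-frequency accuracy,
parameter-distribution summaries, spindle vs non-spindle group tests and
single-parameter shape sweeps — plus EDF/annotation-CSV I/O to apply the
model to real polysomnography.

## Worked example

Fit a simulated spindle corrupted by 10 dB white Gaussian noise
(`python examples/01_simulate_and_fit.py`):

```
converged: True (trf-bounded, 9 evaluations)
param     true   estimate                   95% CI
    a    0.000     0.0061 (  -0.0391,    0.0512)
    b    0.000    -0.0488 (  -0.3846,    0.2869)
    c  -20.000   -20.7437 ( -22.9075,  -18.5800)
    d    0.000    -0.0311 (  -0.0762,    0.0140)
    e   75.000    75.0456 (  74.7099,   75.3814)
    f    0.000     0.5969 (  -1.5665,    2.7603)

GOF: SSE=3.1212  R^2=0.9193  adjR^2=0.9177  RMSE=0.1117  (n=256, m=6, v=250)
```

Every estimate sits inside its confidence interval and close to the
generating value; the R² ≈ 0.92 against the *noisy* input is exactly what a
correct fit should leave on the table at 10 dB — the remaining variance is
noise, not model error. The envelope parameters (`c`) and sweep rate (`f`)
carry the widest intervals, the same parameters that degrade first under
background interference (`examples/03_delta_background.py`).

The other examples, one capability each, are in `examples/`; all print a
short interpretation with their numbers.

The same fit from the shell:

```sh
qpspindle simulate --a 0 --c -20 --e 75 --out spindle.csv
qpspindle fit --input spindle.csv
```

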