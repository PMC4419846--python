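"""Validate fits through their implied spindle energy and frequency.

When true parameters are unknown (real EEG), a fit is validated by comparing
two model-derived quantities against their signal-side counterparts:
energy (area under the model envelope vs area under the Hilbert envelope)
and frequency (e/2pi vs the dominant spectral peak). On a clean synthetic
cohort both errors should be small: the mean frequency error stays well
under 1% and the energy error under a few percent.
"""

import numpy as np

from qpspindle import QPSParams, evaluate_energy_frequency, fit_qps, simulate_spindle

rng = np.random.default_rng(31)
fits, segments = [], []
for _ in range(30):
    params = QPSParams(
        a=rng.uniform(0, 3),
        b=rng.uniform(-2, 2),
        c=rng.uniform(-50, -15),
        d=rng.uniform(-np.pi, np.pi),
        e=2 * np.pi * rng.uniform(11, 16),
        f=rng.uniform(-15, 15),
    )
    seg = simulate_spindle(params)
    segments.append(seg)
    fits.append(fit_qps(seg))

table, means = evaluate_energy_frequency(fits, segments)

print(table.head(5).to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("...")
print(f"\nmean energy error:    {means['mean_energy_error_pct']:.3f} %")
print(f"mean frequency error: {means['mean_frequency_error_pct']:.3f} %")
print(f"spindles evaluated:   {means['n_spindles']:.0f} (excluded: {means['n_excluded']:.0f})")
print(
    "\nOn noise-free spindles the fit is exact, so both errors reflect only "
    "the measurement pipeline: energy agrees almost perfectly, while the "
    "frequency comparison is limited by the spectral peak's position "
    "(sweep rate f shifts it slightly away from the carrier e/2pi)."
)
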