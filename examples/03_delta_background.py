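"""Parameter recovery when the spindle rides on strong delta-band background.

The skewed test spindle (a=5, b=4, c=-30, d=1, e=70, f=5) is mixed with 190
independent delta-band (0.5-4 Hz) surrogates, each scaled to the spindle's
RMS and amplified by a factor of 2 before addition, then refit. Because the
background power sits far below the sigma band, the mean estimates stay
close to truth; the envelope curvature c and sweep rate f show the widest
scale-normalized spread.
"""

from qpspindle import ExperimentConfig, background_robustness
from qpspindle.experiments import DELTA_STUDY_SPINDLE

config = ExperimentConfig(
    seed=101, n_trials=190, true_params=DELTA_STUDY_SPINDLE, background_gain=2.0
)
summary = background_robustness(config)

cols = ["parameter", "true", "mean", "min", "max", "std", "pct_diff_mean"]
print(summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
spread = (summary.set_index("parameter")["std"] / summary.set_index("parameter")["true"].abs())
print("\nscale-normalized spread (std / |true|):")
print(spread.to_string(float_format=lambda v: f"{v:.5f}"))
print(
    "\npct_diff_mean is the percent difference between the mean estimate and "
    "the true value; the largest relative spread lands on f and c, the two "
    "parameters most sensitive to background interference."
)
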