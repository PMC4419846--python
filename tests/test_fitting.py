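"""NLLS estimation, goodness of fit and signal-side reference quantities."""

import math

import numpy as np
import pytest

from qpspindle import (
    QPSParams,
    Segment,
    add_white_noise,
    canonicalize_params,
    dominant_frequency,
    fit_qps,
    goodness_of_fit,
    initial_params,
    model_energy,
    signal_energy,
    simulate_spindle,
)
from qpspindle.model import centered_times

from conftest import random_spindle_params


class TestInitialParams:
    def test_spindle_like_default(self, benchmark_segment):
        init = initial_params(benchmark_segment)
        assert init.a == pytest.approx(0.0, abs=1e-12)  # ln of unit peak
        assert (init.b, init.c, init.d, init.f) == (0.0, -20.0, 0.0, 0.0)
        assert init.e == pytest.approx(2 * math.pi * 13.0)

    def test_amplitude_tracks_data_peak(self, benchmark_segment):
        scaled = benchmark_segment.copy_with(20.0 * benchmark_segment.samples)
        assert initial_params(scaled).a == pytest.approx(math.log(20.0))

    def test_zeros_mode(self, benchmark_segment):
        init = initial_params(benchmark_segment, mode="zeros")
        assert init == QPSParams(0, 0, 0, 0, 0, 0)

    def test_all_zero_segment_rejected(self, benchmark_segment):
        silent = benchmark_segment.copy_with(np.zeros(benchmark_segment.n))
        with pytest.raises(ValueError, match="all-zero"):
            initial_params(silent)


class TestFitQPS:
    def test_noiseless_fit_recovers_truth(self, benchmark_params, benchmark_segment):
        fit = fit_qps(benchmark_segment)
        assert fit.converged
        truth = benchmark_params.as_array()
        np.testing.assert_allclose(fit.params.as_array(), truth, atol=1e-4)
        assert fit.gof.sse < 1e-12

    def test_ci_brackets_estimate(self, benchmark_segment):
        noisy = add_white_noise(benchmark_segment, 10.0, seed=21)
        fit = fit_qps(noisy)
        assert fit.converged and fit.ci_available
        raw = fit.params_raw
        for name in "abcdef":
            lo, hi = fit.ci95[name]
            assert lo <= getattr(raw, name) <= hi

    def test_ten_db_estimates_in_plausible_range(self, benchmark_segment):
        noisy = add_white_noise(benchmark_segment, 10.0, seed=5)
        fit = fit_qps(noisy)
        assert fit.converged
        assert -25 < fit.params.c < -15
        assert 73 < fit.params.e < 77

    def test_unbounded_path_is_levenberg_marquardt(self, benchmark_segment):
        fit = fit_qps(benchmark_segment, bounds=None)
        assert fit.method == "lm"
        np.testing.assert_allclose(
            fit.params.as_array(), [0, 0, -20, 0, 75, 0], atol=1e-6
        )

    def test_roundtrip_identifiability(self, rng):
        # random canonical spindle-range draws, noiseless data: the fit must
        # recover the generating parameters after canonicalization
        for params in random_spindle_params(rng, n=25):
            seg = simulate_spindle(params)
            fit = fit_qps(seg)
            est = canonicalize_params(fit.params).as_array()
            truth = params.as_array()
            rel = np.abs(est - truth) / np.maximum(np.abs(truth), 1e-9)
            # compare the phase circularly
            d_err = abs((est[3] - truth[3] + math.pi) % (2 * math.pi) - math.pi)
            assert np.all(rel[[0, 1, 2, 4, 5]] < 1e-3)
            assert d_err < 1e-3 * max(abs(truth[3]), 1.0)

    def test_init_robustness_at_moderate_snr(self, benchmark_segment):
        # perturbed spindle-like starts must agree on (c, e) within the
        # single-fit confidence-interval widths in >= 90% of trials
        base = initial_params(benchmark_segment)
        perturbed = [
            QPSParams(base.a + da, base.b, base.c * sc, base.d, base.e + de, base.f)
            for da, sc, de in [
                (0.0, 1.0, 0.0),
                (0.5, 0.8, 2 * math.pi),
                (-0.5, 1.3, -2 * math.pi),
                (0.3, 0.6, 2 * math.pi * 1.5),
                (-0.3, 1.5, -2 * math.pi * 1.5),
            ]
        ]
        ci_width_c, ci_width_e = 2.0, 0.32  # printed single-fit CI widths
        n_agree = 0
        n_trials = 10
        for trial in range(n_trials):
            noisy = add_white_noise(benchmark_segment, 10.0, seed=100 + trial)
            fits = [fit_qps(noisy, init=init) for init in perturbed]
            cs = [f.params.c for f in fits]
            es = [f.params.e for f in fits]
            if np.ptp(cs) <= ci_width_c and np.ptp(es) <= ci_width_e:
                n_agree += 1
        assert n_agree >= 0.9 * n_trials

    def test_nonconvergence_is_flagged_not_raised(self, benchmark_segment):
        noisy = add_white_noise(benchmark_segment, 0.0, seed=1)
        fit = fit_qps(noisy, max_iter=3)
        assert not fit.converged

    def test_deterministic(self, benchmark_segment):
        noisy = add_white_noise(benchmark_segment, 5.0, seed=9)
        a = fit_qps(noisy)
        b = fit_qps(noisy)
        np.testing.assert_array_equal(a.params.as_array(), b.params.as_array())


class TestGoodnessOfFit:
    def test_perfect_fit(self, benchmark_segment):
        y = benchmark_segment.samples
        gof = goodness_of_fit(y, y)
        assert gof.sse == 0.0
        assert gof.rsquare == 1.0
        assert gof.rmse == 0.0

    def test_mean_predictor_gives_zero_rsquare(self, benchmark_segment):
        y = benchmark_segment.samples
        gof = goodness_of_fit(y, np.full_like(y, y.mean()))
        assert gof.rsquare == pytest.approx(0.0, abs=1e-12)

    def test_rmse_arithmetic(self):
        # SSE = 2.5 split over 256 samples -> RMSE = sqrt(2.5 / 250) = 0.1
        y = np.zeros(256)
        yhat = y.copy()
        yhat[:250] = math.sqrt(2.5 / 250)
        y[0] = 1.0
        yhat[0] += y[0]  # keep residual structure: sum of squares 2.5
        gof = goodness_of_fit(y, yhat, m=6)
        assert gof.sse == pytest.approx(2.5)
        assert gof.rmse == pytest.approx(0.1)
        assert (gof.n, gof.m, gof.v) == (256, 6, 250)

    def test_dof_identities(self, rng):
        for _ in range(20):
            y = rng.normal(size=100)
            yhat = y + rng.normal(scale=0.3, size=100)
            gof = goodness_of_fit(y, yhat, m=6)
            assert gof.rmse**2 * gof.v == pytest.approx(gof.sse, rel=1e-14)
            assert gof.adj_rsquare == pytest.approx(
                1 - (1 - gof.rsquare) * (gof.n - 1) / gof.v, rel=1e-12
            )

    def test_constant_observed_flagged(self):
        gof = goodness_of_fit(np.ones(50), np.ones(50) * 1.1, m=6)
        assert math.isnan(gof.rsquare)
        assert not gof.rsquare_defined

    def test_requires_more_samples_than_coefficients(self):
        with pytest.raises(ValueError, match="n > m"):
            goodness_of_fit(np.zeros(6), np.zeros(6), m=6)


class TestSignalEnergy:
    def test_pure_sinusoid_area(self):
        fs, T, A = 256.0, 2.0, 1.5
        t = np.arange(int(fs * T)) / fs
        seg = Segment(A * np.sin(2 * math.pi * 13 * t), fs, t0=0.0)
        assert signal_energy(seg) == pytest.approx(A * T, rel=0.02)

    def test_agrees_with_model_envelope_area(self, benchmark_params):
        seg = simulate_spindle(benchmark_params)
        window = (float(seg.times[0]), float(seg.times[-1]))
        assert signal_energy(seg) == pytest.approx(
            model_energy(benchmark_params, window), rel=0.05
        )

    def test_linearity(self, benchmark_segment):
        doubled = benchmark_segment.copy_with(2.0 * benchmark_segment.samples)
        assert signal_energy(doubled) == pytest.approx(
            2.0 * signal_energy(benchmark_segment), rel=1e-12
        )


class TestDominantFrequency:
    def test_pure_tone(self):
        t = centered_times(256, 256.0)
        seg = Segment(np.sin(2 * math.pi * 13.0 * t), 256.0, t0=float(t[0]))
        assert dominant_frequency(seg, band=(9, 18)) == pytest.approx(
            13.0, abs=256 / 4096
        )

    def test_clean_qps_matches_carrier(self, benchmark_segment):
        got = dominant_frequency(benchmark_segment)
        assert got == pytest.approx(75 / (2 * math.pi), abs=256 / 4096)

    def test_out_of_band_component_rejected(self):
        t = centered_times(512, 256.0)
        samples = 2 * np.sin(2 * math.pi * 13 * t) + 1 * np.sin(2 * math.pi * 3 * t)
        seg = Segment(samples, 256.0, t0=float(t[0]))
        assert dominant_frequency(seg, band=(9, 18)) == pytest.approx(13.0, abs=0.1)

    def test_flat_spectrum_rejected(self):
        seg = Segment(np.zeros(256), 256.0, t0=-0.5)
        with pytest.raises(ValueError, match="flat"):
            dominant_frequency(seg)
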