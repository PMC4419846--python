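"""Synthetic inputs for the validation experiments.

Everything the experiments need is generated here without external data:
clean QPS spindles on a centered time axis, white Gaussian noise at a
requested SNR, band-limited delta (0.5-4 Hz) background surrogates standing
in for raw EEG with strong slow-wave activity, and 1/f "pink" broadband
surrogates used as non-spindle EEG stand-ins. All generators are pure
functions of their arguments and a seed: same inputs, bitwise-same output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from qpspindle.model import QPSParams, Segment, centered_times, qps_evaluate

__all__ = [
    "NoiseSpec",
    "simulate_spindle",
    "add_white_noise",
    "synth_background",
    "mix_background",
]

DELTA_BAND = (0.5, 4.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Declarative description of a noise source.

    kind is one of ``white`` (Gaussian, SNR-controlled), ``delta_band``
    (band-limited Gaussian surrogate for slow-wave background) or
    ``pink_broadband`` (1/f spectrum, the non-spindle surrogate). ``snr_db``
    applies to white noise; ``gain``/``rms`` to the background kinds.
    """

    kind: str
    snr_db: float | None = None
    gain: float | None = None
    rms: float | None = None
    band: tuple[float, float] = DELTA_BAND
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "delta_band", "pink_broadband"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def simulate_spindle(params: QPSParams, n: int = 256, fs: float = 256.0) -> Segment:
    """Noise-free QPS spindle on a centered time axis (t=0 at index n//2)."""
    t = centered_times(n, fs)
    samples = qps_evaluate(params, t)
    return Segment(samples, fs, t0=float(t[0]), meta={"params": params})


def add_white_noise(segment: Segment, snr_db: float, seed: int) -> Segment:
    """Add zero-mean white Gaussian noise at the requested SNR.

    Noise variance is P_signal / 10**(snr_db/10) with P_signal the mean
    squared sample value. The achieved empirical SNR of the realization is
    recorded in the output metadata under ``achieved_snr_db``.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    p_signal = float(np.mean(segment.samples**2))
    if p_signal == 0.0:
        raise ValueError("cannot set an SNR on a zero-power segment")
    noise_var = p_signal / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(noise_var), segment.n)
    p_noise = float(np.mean(noise**2))
    achieved = 10.0 * np.log10(p_signal / p_noise) if p_noise > 0 else np.inf
    return segment.copy_with(
        segment.samples + noise,
        snr_db=snr_db,
        achieved_snr_db=achieved,
        noise_seed=seed,
    )


def _pink_spectrum_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    # Shape white noise to a 1/f amplitude spectrum; DC removed.
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    return np.fft.irfft(spec * scale, n)


def synth_background(
    kind: str,
    n: int,
    fs: float,
    rms: float,
    seed: int,
    band: tuple[float, float] = DELTA_BAND,
) -> Segment:
    """Background EEG surrogate scaled to a requested RMS amplitude.

    ``delta_band``: Gaussian white noise band-passed (zero-phase 4th-order
    Butterworth) to ``band`` (default 0.5-4 Hz), emulating slow-wave
    background. ``pink_broadband``: 1/f-spectrum noise, a generic unmarked-
    EEG surrogate. The filter transient is avoided by generating padding on
    both sides and cropping the center, so segments of at least one second
    are required.
    """
    if kind not in ("delta_band", "pink_broadband"):
        raise ValueError(f"unknown background kind {kind!r}")
    if not fs > 0:
        raise ValueError("fs must be positive")
    if n < fs:
        raise ValueError(
            f"background segments need at least 1 s of samples (n >= fs); got n={n} at fs={fs}"
        )
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    if not rms > 0:
        raise ValueError("rms must be positive")
    rng = np.random.default_rng(seed)
    if kind == "delta_band":
        pad = int(2 * fs)
        white = rng.normal(size=n + 2 * pad)
        sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        filtered = sps.sosfiltfilt(sos, white)
        samples = filtered[pad : pad + n]
    else:
        samples = _pink_spectrum_noise(n, rng)
    samples = samples - np.mean(samples)
    samples = samples * (rms / np.sqrt(np.mean(samples**2)))
    t = centered_times(n, fs)
    return Segment(
        np.asarray(samples),
        fs,
        t0=float(t[0]),
        meta={"kind": kind, "rms": rms, "seed": seed, "band": band},
    )


def mix_background(spindle: Segment, background: Segment, gain: float) -> Segment:
    """samples = spindle + gain * background (the additive mixing protocol)."""
    if spindle.n != background.n:
        raise ValueError(f"length mismatch: {spindle.n} vs {background.n}")
    if spindle.fs != background.fs:
        raise ValueError(f"sampling-rate mismatch: {spindle.fs} vs {background.fs}")
    return spindle.copy_with(
        spindle.samples + gain * background.samples,
        background_kind=background.meta.get("kind"),
        background_gain=gain,
    )
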