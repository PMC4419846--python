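"""The quadratic-parameter sinusoid model and its closed-form quantities.

The QPS waveform is ``s(t) = exp(a + b t + c t^2) cos(d + e t + f t^2)``.
Time is in seconds with ``t = 0`` at the analysis-window center, so ``a`` is
the log-amplitude at the window center, ``e`` the angular frequency there
(rad/s) and the instantaneous frequency ``(e + 2 f t) / (2 pi)`` Hz is linear
in time. Spindle-shaped signals have ``c < 0`` (Gaussian-like decaying
envelope) and ``e`` in the sigma band, roughly ``2 pi * [11, 16]`` rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, special

__all__ = [
    "QPSParams",
    "Segment",
    "qps_evaluate",
    "envelope_and_phase",
    "model_energy",
    "model_frequency",
    "canonicalize_params",
]

# Treat |c| below this as "no curvature": the erf closed form divides by
# sqrt(-c) and loses all precision there.
_C_DEGENERATE = 1e-9


@dataclass(frozen=True)
class QPSParams:
    """The six QPS parameters.

    Attributes
    ----------
    a : float
        Log-amplitude at t = 0 (log of signal units, dimensionless).
    b : float
        Log-amplitude rate of change (1/s); skews the envelope in time.
    c : float
        Gaussian envelope curvature (1/s^2); negative for decaying,
        spindle-like envelopes.
    d : float
        Initial phase at t = 0 (rad).
    e : float
        Angular frequency at t = 0 (rad/s); e/(2 pi) is the carrier
        frequency in Hz.
    f : float
        Angular frequency rate (rad/s^2); the instantaneous frequency
        changes linearly at 2 f rad/s per second.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f], dtype=float)

    @classmethod
    def from_array(cls, values) -> "QPSParams":
        a, b, c, d, e, f = (float(v) for v in values)
        return cls(a, b, c, d, e, f)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


PARAM_NAMES = ("a", "b", "c", "d", "e", "f")


@dataclass
class Segment:
    """A uniformly sampled real-valued signal with a centered time axis.

    ``times[k] = t0 + k / fs``; by convention the axis is centered so that
    t = 0 falls at the segment midpoint (the Taylor-expansion center of the
    model). ``t_c`` records where that center sits in the source recording,
    when the segment was cut from one.
    """

    samples: np.ndarray
    fs: float
    t0: float
    t_c: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("Segment needs a 1-D array of at least 2 samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def copy_with(self, samples: np.ndarray, **meta) -> "Segment":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Segment(np.asarray(samples, dtype=float), self.fs, self.t0, self.t_c, new_meta)


def centered_times(n: int, fs: float) -> np.ndarray:
    """Centered time axis: n samples at fs with t = 0 at index n//2.

    For the default n=256 at 256 Hz this is the half-open window
    [-0.5, 0.5) s.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not fs > 0:
        raise ValueError("fs must be positive")
    return (np.arange(n) - n // 2) / fs


def _check_params(params: QPSParams) -> None:
    if not isinstance(params, QPSParams):
        raise TypeError(f"expected QPSParams, got {type(params).__name__}")
    if not params.is_finite():
        raise ValueError(f"non-finite QPS parameters: {params}")


def qps_evaluate(params: QPSParams, times) -> np.ndarray:
    """Evaluate the QPS waveform exp(a+bt+ct^2) cos(d+et+ft^2) elementwise."""
    _check_params(params)
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    log_amp = params.a + params.b * t + params.c * t * t
    phase = params.d + params.e * t + params.f * t * t
    return np.exp(log_amp) * np.cos(phase)


def envelope_and_phase(params: QPSParams, times):
    """Return (envelope, phase in rad, instantaneous frequency in Hz).

    envelope = exp(a + b t + c t^2); phase = d + e t + f t^2; the
    instantaneous frequency is the phase derivative over 2 pi,
    (e + 2 f t) / (2 pi).
    """
    _check_params(params)
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    envelope = np.exp(params.a + params.b * t + params.c * t * t)
    phase = params.d + params.e * t + params.f * t * t
    inst_freq_hz = (params.e + 2.0 * params.f * t) / (2.0 * math.pi)
    return envelope, phase, inst_freq_hz


def model_energy(params: QPSParams, window: tuple[float, float]) -> float:
    """Area under the model envelope over ``window`` (signal units * s).

    Computes ``integral of exp(a + b t + c t^2) dt`` on [t_lo, t_hi]. For
    c < 0 the Gaussian integral has the closed form

        exp(a - b^2/(4c)) * sqrt(pi / -c) / 2
            * [erf(sqrt(-c) (t_hi - mu)) - erf(sqrt(-c) (t_lo - mu))]

    with envelope peak time mu = -b / (2c). For c within rounding of zero
    (or positive) the closed form is ill-conditioned and adaptive quadrature
    is used instead.
    """
    _check_params(params)
    t_lo, t_hi = float(window[0]), float(window[1])
    if not t_lo < t_hi:
        raise ValueError(f"window must satisfy t_lo < t_hi, got {window}")
    a, b, c = params.a, params.b, params.c
    if c < -_C_DEGENERATE:
        k = -c
        mu = b / (2.0 * k)
        amp = math.exp(a + b * b / (4.0 * k))
        root_k = math.sqrt(k)
        area = (
            amp
            * 0.5
            * math.sqrt(math.pi / k)
            * (special.erf(root_k * (t_hi - mu)) - special.erf(root_k * (t_lo - mu)))
        )
        return float(area)
    value, _ = integrate.quad(lambda t: math.exp(a + b * t + c * t * t), t_lo, t_hi)
    return float(value)


def model_frequency(params: QPSParams) -> float:
    """Carrier frequency e / (2 pi) in Hz; requires canonical form (e > 0)."""
    _check_params(params)
    if params.e <= 0:
        raise ValueError(
            f"e = {params.e} is not canonical (e > 0 required); "
            "apply canonicalize_params first"
        )
    return params.e / (2.0 * math.pi)


def _wrap_phase(d: float) -> float:
    """Wrap a phase to (-pi, pi]."""
    wrapped = (d + math.pi) % (2.0 * math.pi) - math.pi
    if wrapped == -math.pi:
        wrapped = math.pi
    return wrapped


def canonicalize_params(params: QPSParams) -> QPSParams:
    """Return the canonical equivalent parameter set (same waveform).

    The QPS is invariant under (d, e, f) -> (-d, -e, -f) (cosine evenness)
    and under d -> d + 2 pi k; the canonical representative has e > 0
    (e >= 0 when e is exactly zero) and d in (-pi, pi]. a, b, c are
    untouched.
    """
    _check_params(params)
    d, e, f = params.d, params.e, params.f
    if e < 0 or (e == 0 and f < 0):
        d, e, f = -d, -e, -f
    d = _wrap_phase(d)
    if d == params.d and e == params.e and f == params.f:
        return params
    return replace(params, d=d, e=e, f=f)
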