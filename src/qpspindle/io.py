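"""File I/O: EDF recordings, annotation CSVs, segments and fit results.

Annotations are 0-based seconds from recording start with half-open extents
[onset, onset + duration); extracted segments get a centered time axis
(t = 0 at the annotation midpoint t_c), matching the model's
Taylor-expansion-center convention. Segment CSV and fit-result JSON
round-trip losslessly (floats serialized at 17 significant digits).
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sps

from qpspindle.model import PARAM_NAMES, QPSParams, Segment
from qpspindle.fitting import FitResult, GOFMetrics

__all__ = [
    "AnnotationRecord",
    "read_edf_channel",
    "write_edf",
    "read_annotations",
    "bandpass_spindle",
    "extract_segments",
    "segment_to_csv",
    "segment_from_csv",
    "fit_result_to_json",
    "fit_result_from_json",
]

logger = logging.getLogger("qpspindle")

# AASM-plausible spindle duration range (s); outside it we warn, not reject.
SPINDLE_DURATION_RANGE = (0.5, 2.0)
SIGMA_BAND_HZ = (11.0, 16.0)


@dataclass(frozen=True)
class AnnotationRecord:
    """One scored spindle interval."""

    channel: str
    onset: float
    duration: float
    scorer: str

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")

    @property
    def midpoint(self) -> float:
        return self.onset + self.duration / 2.0


def read_edf_channel(path, channel: str) -> tuple[np.ndarray, float]:
    """Read one channel from an EDF recording; returns (samples in uV, fs)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not found; available channels: {raw.ch_names}"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    samples = raw.get_data(units="uV")[0]
    return np.asarray(samples, dtype=float), float(raw.info["sfreq"])


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    channel: str = "EEG C3",
    physical_range: tuple[float, float] | None = None,
) -> None:
    """Write a single-channel 16-bit EDF file (synthetic-fixture writer).

    A minimal standard-EDF encoder intended for generating synthetic test
    recordings, not for clinical data. Samples are in uV; values are
    quantized to the 16-bit digital range mapped onto ``physical_range``
    (default: symmetric around the data extremum).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("expected a 1-D sample array")
    if not float(fs).is_integer():
        raise ValueError("this writer only supports integer sampling rates")
    fs = int(fs)
    n_records = int(math.ceil(samples.size / fs))
    padded = np.zeros(n_records * fs)
    padded[: samples.size] = samples
    if physical_range is None:
        extremum = float(np.max(np.abs(padded))) or 1.0
        physical_range = (-extremum, extremum)
    phys_min, phys_max = physical_range
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((padded - phys_min) * scale) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def fixed(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            fixed("0", 8),  # version
            fixed("X X X X", 80),  # patient id (anonymous)
            fixed("Startdate X X X X", 80),  # recording id
            fixed("01.01.00", 8),
            fixed("00.00.00", 8),
            fixed(str(256 + 256), 8),  # header bytes: 256 + 256 per signal
            fixed("", 44),
            fixed(str(n_records), 8),
            fixed("1", 8),  # record duration, s
            fixed("1", 4),  # number of signals
        ]
    )
    signal_header = b"".join(
        [
            fixed(channel, 16),
            fixed("Synthetic", 80),
            fixed("uV", 8),
            fixed(f"{phys_min:.6g}", 8),
            fixed(f"{phys_max:.6g}", 8),
            fixed(str(dig_min), 8),
            fixed(str(dig_max), 8),
            fixed("", 80),
            fixed(str(fs), 8),
            fixed("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(digital.tobytes())


def read_annotations(path) -> list[AnnotationRecord]:
    """Parse a spindle-annotation CSV with header channel,onset,duration,scorer.

    Onset and duration are seconds from recording start. Durations outside
    the plausible spindle range (0.5-2 s) produce a warning but are kept.
    Malformed rows raise with the offending line number.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["channel", "onset", "duration", "scorer"]
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != expected:
            raise ValueError(
                f"{path}: expected header {','.join(expected)}, got {reader.fieldnames}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                record = AnnotationRecord(
                    channel=row["channel"].strip(),
                    onset=float(row["onset"]),
                    duration=float(row["duration"]),
                    scorer=row["scorer"].strip(),
                )
            except (TypeError, ValueError, AttributeError) as exc:
                raise ValueError(f"{path}:{line_no}: malformed annotation row: {row}") from exc
            lo, hi = SPINDLE_DURATION_RANGE
            if not lo <= record.duration <= hi:
                warnings.warn(
                    f"{path}:{line_no}: duration {record.duration} s outside the "
                    f"plausible spindle range [{lo}, {hi}] s",
                    stacklevel=2,
                )
            records.append(record)
    return records


def bandpass_spindle(
    signal: np.ndarray,
    fs: float,
    low: float = SIGMA_BAND_HZ[0],
    high: float = SIGMA_BAND_HZ[1],
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (default sigma band 11-16 Hz).

    Forward-backward filtering doubles the effective order and cancels phase
    distortion, so in-band peak positions are preserved.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band ({low}, {high}) must lie inside (0, fs/2)")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt pads by 3 * (2 * sections + 1) samples on each side
    padlen = 3 * (2 * sos.shape[0] + 1)
    if signal.size <= 3 * padlen:
        raise ValueError(
            f"signal of {signal.size} samples too short for stable zero-phase "
            f"filtering (need > {3 * padlen})"
        )
    return sps.sosfiltfilt(sos, signal)


def extract_segments(
    signal: np.ndarray,
    fs: float,
    annotations: list[AnnotationRecord],
    window_mode: str = "fixed_1s",
) -> list[Segment]:
    """Cut annotated spindles out of a recording as centered Segments.

    Each segment is centered on the annotation midpoint t_c. ``fixed_1s``
    takes round(fs) samples regardless of the marked duration;
    ``annotation_span`` takes round(duration * fs). Annotations that do not
    fit inside the recording are skipped with a log entry.
    """
    if window_mode not in ("fixed_1s", "annotation_span"):
        raise ValueError(f"unknown window mode {window_mode!r}")
    signal = np.asarray(signal, dtype=float)
    segments: list[Segment] = []
    for ann in annotations:
        if window_mode == "fixed_1s":
            n = int(round(fs))
        else:
            n = int(round(ann.duration * fs))
        if n < 2:
            logger.warning("annotation at %.3f s too short (%d samples); skipped", ann.onset, n)
            continue
        center_idx = int(round(ann.midpoint * fs))
        start = center_idx - n // 2
        stop = start + n
        if start < 0 or stop > signal.size:
            logger.warning(
                "annotation at %.3f s (+%.3f s) exceeds recording bounds; skipped",
                ann.onset,
                ann.duration,
            )
            continue
        t0 = (start - center_idx) / fs
        segments.append(
            Segment(
                signal[start:stop].copy(),
                fs,
                t0=t0,
                t_c=center_idx / fs,
                meta={"channel": ann.channel, "scorer": ann.scorer, "onset": ann.onset,
                      "duration": ann.duration},
            )
        )
    return segments


def segment_to_csv(segment: Segment, path) -> None:
    """Write a segment as CSV (time,value rows plus fs/t0/t_c header comments)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={segment.fs!r} t0={segment.t0!r} t_c={segment.t_c!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(segment.times, segment.samples):
            writer.writerow([repr(float(t)), repr(float(v))])


def segment_from_csv(path) -> Segment:
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        meta = dict(item.split("=", 1) for item in first[1:].split())
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["time_s", "value"]:
            raise ValueError(f"{path}: unexpected header {header}")
        values = [float(row[1]) for row in reader if row]
    return Segment(
        np.array(values),
        fs=float(meta["fs"]),
        t0=float(meta["t0"]),
        t_c=float(meta["t_c"]),
    )


def _params_dict(params: QPSParams) -> dict:
    return {name: getattr(params, name) for name in PARAM_NAMES}


def fit_result_to_json(fit: FitResult, path=None) -> str:
    """Serialize a FitResult to JSON (optionally also writing to path)."""
    payload = {
        "params": _params_dict(fit.params),
        "params_raw": _params_dict(fit.params_raw),
        "ci95": {k: list(v) for k, v in fit.ci95.items()},
        "ci_available": fit.ci_available,
        "gof": {
            "sse": fit.gof.sse,
            "sst": fit.gof.sst,
            "rsquare": fit.gof.rsquare,
            "adj_rsquare": fit.gof.adj_rsquare,
            "rmse": fit.gof.rmse,
            "n": fit.gof.n,
            "m": fit.gof.m,
            "v": fit.gof.v,
        },
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "init_used": _params_dict(fit.init_used),
        "init_mode": fit.init_mode,
        "method": fit.method,
        "fallback_used": fit.fallback_used,
        "residuals": [float(r) for r in fit.residuals],
    }
    text = json.dumps(payload, indent=2, allow_nan=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_result_from_json(source) -> FitResult:
    """Inverse of :func:`fit_result_to_json`; accepts a path or a JSON string."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    data = json.loads(text)
    gof = GOFMetrics(**data["gof"])
    return FitResult(
        params=QPSParams(**data["params"]),
        params_raw=QPSParams(**data["params_raw"]),
        ci95={k: tuple(v) for k, v in data["ci95"].items()},
        ci_available=data["ci_available"],
        gof=gof,
        converged=data["converged"],
        n_iter=data["n_iter"],
        init_used=QPSParams(**data["init_used"]),
        init_mode=data["init_mode"],
        method=data["method"],
        fallback_used=data.get("fallback_used", False),
        residuals=np.array(data["residuals"]),
    )
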