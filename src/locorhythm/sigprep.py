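"""Preprocessing of raw neurogram/EMG traces.

The chain turns a raw multi-kHz voltage trace into the smoothed, zero-mean,
100-Hz signal on which correlogram analysis operates: window the recording
into 60-s intervals, full-wave rectify, low-pass filter and resample to
100 Hz, subtract the mean, then smooth with a 13-point third-order
Savitzky-Golay filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "TimeSeriesRecording",
    "ProcessedSegment",
    "rectify",
    "lowpass_resample",
    "savitzky_golay_smooth",
    "preprocess",
]

SG_WINDOW = 13
SG_ORDER = 3


@dataclass
class TimeSeriesRecording:
    """Raw multi-channel voltage trace.

    samples is a (n_channels, n_samples) float array in arbitrary units.
    """

    sample_rate_hz: float
    channel_labels: list[str]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels must match number of sample rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass
class ProcessedSegment:
    """One analysis window after the full preprocessing chain.

    Channels are zero-mean (to within numerical tolerance) and sampled at
    ``sample_rate_hz`` (100 Hz by default after resampling).
    """

    window_start_s: float
    window_length_s: float
    sample_rate_hz: float
    channel_labels: list[str]
    samples: np.ndarray
    params: dict | None = None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


def rectify(trace: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    return np.abs(trace)


def lowpass_resample(
    trace: np.ndarray,
    fs_in: float,
    cutoff_hz: float = 5.0,
    fs_out: float = 100.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase low-pass filter then resample to ``fs_out``.

    A 4th-order Butterworth applied forward-backward (zero phase, DC gain
    1) provides anti-aliasing beyond the polyphase resampler's own FIR.
    Output length is round(n * fs_out / fs_in).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace must be non-empty")
    if cutoff_hz >= fs_in / 2:
        raise ValueError("cutoff_hz must be below the input Nyquist frequency")
    if fs_out > fs_in:
        raise ValueError("fs_out must not exceed fs_in")

    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_in, output="sos")
    filtered = signal.sosfiltfilt(sos, trace)

    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    if up == down:
        return filtered
    out = signal.resample_poly(filtered, up, down, padtype="line")
    n_target = int(round(len(trace) * fs_out / fs_in))
    return out[:n_target] if len(out) >= n_target else np.pad(out, (0, n_target - len(out)), mode="edge")


def savitzky_golay_smooth(trace: np.ndarray) -> np.ndarray:
    """13-point, 3rd-order Savitzky-Golay smoothing, mirror-padded edges."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < SG_WINDOW:
        raise ValueError(f"trace must have at least {SG_WINDOW} samples")
    return signal.savgol_filter(trace, SG_WINDOW, SG_ORDER, mode="mirror")


def preprocess(
    recording: TimeSeriesRecording,
    window_start_s: float = 0.0,
    window_length_s: float = 60.0,
    cutoff_hz: float = 5.0,
    fs_out: float = 100.0,
) -> ProcessedSegment:
    """Run the full chain on one window of a recording.

    Order: window -> rectify -> low-pass + resample to ``fs_out`` ->
    mean subtraction -> Savitzky-Golay smoothing.  Mirror-edge smoothing
    can shift the mean by a tiny amount, so the mean is removed once more
    after smoothing to keep each channel exactly zero-mean.
    """
    fs = recording.sample_rate_hz
    i0 = int(round(window_start_s * fs))
    i1 = int(round((window_start_s + window_length_s) * fs))
    if window_start_s < 0 or i1 > recording.n_samples or i1 <= i0:
        raise ValueError(
            f"window [{window_start_s}, {window_start_s + window_length_s}) s "
            f"does not fit in the {recording.duration_s:.1f}-s recording"
        )
    out = []
    for row in recording.samples:
        x = rectify(row[i0:i1])
        x = lowpass_resample(x, fs_in=fs, cutoff_hz=cutoff_hz, fs_out=fs_out)
        x = x - x.mean()
        x = savitzky_golay_smooth(x)
        x = x - x.mean()
        out.append(x)
    return ProcessedSegment(
        window_start_s=window_start_s,
        window_length_s=window_length_s,
        sample_rate_hz=fs_out,
        channel_labels=list(recording.channel_labels),
        samples=np.vstack(out),
        params={"cutoff_hz": cutoff_hz, "filter": "butterworth4_zero_phase",
                "fs_out": fs_out, "sg_window": SG_WINDOW, "sg_order": SG_ORDER},
    )


def iter_windows(recording: TimeSeriesRecording, window_length_s: float = 60.0):
    """Yield start times of non-overlapping windows tiling from t = 0.

    Partial trailing windows are dropped.
    """
    n_win = int(recording.duration_s // window_length_s)
    for k in range(n_win):
        yield k * window_length_s
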