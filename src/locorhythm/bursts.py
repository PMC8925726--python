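"""Burst detection and burst-onset circular statistics.

A burst is one epoch of elevated envelope activity per locomotor cycle.
Onsets of a target channel's bursts are expressed as phases within the
reference channel's cycle (normalized 0..1), and phase concentration is
summarized by the circular resultant vector and tested for non-uniformity
with Rayleigh's test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BurstTrain",
    "CircularSummary",
    "detect_bursts",
    "burst_phases",
    "circular_summary",
    "rayleigh_p",
    "rayleigh_test",
    "burst_duration_summary",
]


@dataclass
class BurstTrain:
    """Detected bursts of one channel (times in seconds)."""

    channel: str
    onsets_s: np.ndarray
    offsets_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.offsets_s = np.asarray(self.offsets_s, dtype=float)
        if len(self.onsets_s) != len(self.offsets_s):
            raise ValueError("onsets and offsets must have equal length")
        if len(self.onsets_s) > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.offsets_s <= self.onsets_s):
            raise ValueError("each offset must exceed its onset")
        if np.any(self.onsets_s[1:] < self.offsets_s[:-1]):
            raise ValueError("bursts must not overlap")

    @property
    def durations_s(self) -> np.ndarray:
        return self.offsets_s - self.onsets_s

    def __len__(self) -> int:
        return len(self.onsets_s)


@dataclass
class CircularSummary:
    """Circular statistics of a set of phases in [0, 1)."""

    n: int
    phases: np.ndarray
    resultant_length: float
    mean_phase: float
    rayleigh_z: float
    rayleigh_p: float


def detect_bursts(
    trace: np.ndarray,
    sample_rate_hz: float,
    channel: str = "",
    on_frac: float = 0.3,
    off_frac: float = 0.15,
    min_burst_s: float = 0.2,
    min_gap_s: float = 0.2,
) -> BurstTrain:
    """Schmitt-trigger burst detection on a processed envelope.

    A burst starts when the signal exceeds ``on_frac`` x A and ends when
    it falls below ``off_frac`` x A, where A is the robust amplitude (95th
    percentile of the rectified signal).  Gaps shorter than ``min_gap_s``
    are merged and bursts shorter than ``min_burst_s`` dropped.  A flat
    signal yields an empty train.
    """
    x = np.asarray(trace, dtype=float)
    amp = float(np.percentile(np.abs(x), 95))
    if amp == 0.0:
        return BurstTrain(channel, np.array([]), np.array([]))
    hi, lo = on_frac * amp, off_frac * amp

    onsets, offsets = [], []
    inside = False
    start = 0
    for i, v in enumerate(x):
        if not inside and v > hi:
            inside = True
            start = i
        elif inside and v < lo:
            inside = False
            onsets.append(start)
            offsets.append(i)
    if inside:
        onsets.append(start)
        offsets.append(len(x))

    if not onsets:
        return BurstTrain(channel, np.array([]), np.array([]))

    on = np.asarray(onsets, dtype=float) / sample_rate_hz
    off = np.asarray(offsets, dtype=float) / sample_rate_hz

    # merge across short gaps
    merged_on, merged_off = [on[0]], [off[0]]
    for a, b in zip(on[1:], off[1:]):
        if a - merged_off[-1] < min_gap_s:
            merged_off[-1] = b
        else:
            merged_on.append(a)
            merged_off.append(b)
    on = np.asarray(merged_on)
    off = np.asarray(merged_off)

    keep = (off - on) >= min_burst_s
    return BurstTrain(channel, on[keep], off[keep])


def burst_phases(reference: BurstTrain, target: BurstTrain) -> np.ndarray:
    """Phase of each target onset within the reference cycle, in [0, 1).

    A target onset t falling in reference cycle [on_i, on_{i+1}) maps to
    (t - on_i) / (on_{i+1} - on_i); onsets outside all reference cycles
    are dropped.
    """
    ref = reference.onsets_s
    if len(ref) < 2:
        raise ValueError("reference train needs at least 2 onsets")
    t = target.onsets_s
    idx = np.searchsorted(ref, t, side="right") - 1
    ok = (idx >= 0) & (idx < len(ref) - 1)
    idx = idx[ok]
    t = t[ok]
    return (t - ref[idx]) / (ref[idx + 1] - ref[idx])


def rayleigh_p(n: int, rbar: float) -> float:
    """Rayleigh-test p-value via the second-order series approximation.

    Z = n * rbar**2;
    p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)],
    clipped to [0, 1].
    """
    z = n * rbar * rbar
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(min(1.0, max(0.0, p)))


def circular_summary(phases: np.ndarray) -> CircularSummary:
    """Resultant vector, mean phase and Rayleigh statistics of phases."""
    phases = np.asarray(phases, dtype=float) % 1.0
    n = len(phases)
    if n < 1:
        raise ValueError("need at least one phase")
    ang = 2.0 * np.pi * phases
    vec = np.mean(np.exp(1j * ang))
    rbar = float(np.abs(vec))
    mean_phase = float((np.angle(vec) / (2.0 * np.pi)) % 1.0)
    z = n * rbar * rbar
    p = rayleigh_p(n, rbar) if n >= 2 else float("nan")
    return CircularSummary(
        n=n, phases=phases, resultant_length=rbar,
        mean_phase=mean_phase, rayleigh_z=float(z), rayleigh_p=p,
    )


def rayleigh_test(
    summary: CircularSummary,
    method: str = "series",
    n_mc: int = 10000,
    seed: int = 0,
) -> float:
    """Rayleigh test for non-uniformity of the phases in ``summary``.

    method="series" uses the closed-form second-order approximation;
    method="mc" estimates the null distribution of the resultant length
    by Monte-Carlo draws of n uniform phases (useful at very small n,
    where the series is least accurate).
    """
    n = summary.n
    if n < 2:
        raise ValueError("Rayleigh test needs n >= 2")
    if method == "series":
        return rayleigh_p(n, summary.resultant_length)
    if method != "mc":
        raise ValueError("method must be 'series' or 'mc'")
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0.0, 2.0 * np.pi, size=(n_mc, n))
    null_r = np.abs(np.mean(np.exp(1j * ang), axis=1))
    return float((1 + np.sum(null_r >= summary.resultant_length)) / (n_mc + 1))


def burst_duration_summary(train_a: BurstTrain, train_b: BurstTrain) -> dict:
    """Mean/SD burst durations of two trains and their asymmetry ratio.

    Ratio is mean duration of ``train_b`` over mean duration of
    ``train_a`` (>1 when b's bursts are longer).
    """
    if len(train_a) == 0 or len(train_b) == 0:
        raise ValueError("both trains must be non-empty")
    da, db = train_a.durations_s, train_b.durations_s
    return {
        "mean_a_s": float(da.mean()),
        "sd_a_s": float(da.std(ddof=1)) if len(da) > 1 else 0.0,
        "mean_b_s": float(db.mean()),
        "sd_b_s": float(db.std(ddof=1)) if len(db) > 1 else 0.0,
        "ratio_b_over_a": float(db.mean() / da.mean()),
    }
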