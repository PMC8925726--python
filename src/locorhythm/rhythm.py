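"""Correlogram-based rhythm statistics: PTCC, cycle period, phase lag.

The peak-to-trough correlation coefficient (PTCC) measures rhythm
stability from a lagged correlogram: the difference between the
correlation extremum nearest lag 0 and the first following extremum of
the opposite kind.  For a stable in-phase (synchronous) pair the peak at
lag 0 minus the subsequent trough is close to +2; for a stable anti-phase
(alternating) pair the trough at lag 0 minus the subsequent peak is close
to -2, so the sign of the statistic encodes the coordination mode while
its magnitude encodes stability.  A "literal" mode (first positive peak
minus global minimum over the window, always >= 0) is also available.

The cycle period T is the lag of the first off-zero peak of the
autocorrelogram, and the phase lag is the position (mod T, as a fraction
of T) of the cross-correlogram peak that follows the trough nearest
lag 0: ~0 for synchrony, ~0.5 for alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "Correlogram",
    "RhythmMetrics",
    "correlogram",
    "ptcc",
    "cycle_period",
    "phase_lag",
    "classify_coordination",
]

#: PTCC search window: 75 lags of 50 ms each, per the correlogram convention
#: of counting lags in 50-ms steps.
PTCC_WINDOW_S = 75 * 0.05

#: Minimum prominence for a correlogram extremum to count as a peak/trough.
PEAK_PROMINENCE = 0.05

#: Lags with fewer overlapping samples than this are excluded.
MIN_OVERLAP = 10


@dataclass
class Correlogram:
    """Per-lag Pearson correlation between two channels.

    ``lags_s`` is a symmetric grid -L..+L; ``coefficients[i]`` is the
    correlation of x(t) with y(t + lags_s[i]); undefined lags (zero
    variance or insufficient overlap) are NaN.
    """

    pair: tuple[str, str]
    lag_step_s: float
    lags_s: np.ndarray
    coefficients: np.ndarray

    @property
    def is_auto(self) -> bool:
        return self.pair[0] == self.pair[1]

    def at(self, lag_s: float) -> float:
        idx = int(np.argmin(np.abs(self.lags_s - lag_s)))
        return float(self.coefficients[idx])


@dataclass
class RhythmMetrics:
    """Summary rhythm statistics for one channel pair in one window."""

    pair: tuple[str, str]
    ptcc: float | None = None
    cycle_period_s: float | None = None
    phase_lag_cycles: float | None = None
    coordination: str = "indeterminate"
    flags: list[str] = field(default_factory=list)


def correlogram(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate_hz: float,
    max_lag_s: float,
    lag_step_s: float | None = None,
    pair: tuple[str, str] = ("x", "y"),
) -> Correlogram:
    """Lagged Pearson correlogram of two equal-length zero-mean signals.

    C(l) is computed on the overlapping portions of x and y shifted by l,
    at every multiple of ``lag_step_s`` in [-max_lag_s, +max_lag_s].  The
    step defaults to the sampling interval and must be a multiple of it.
    x is y yields an autocorrelogram (C(0) = 1, symmetric).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    dt = 1.0 / sample_rate_hz
    if max_lag_s >= n * dt / 2:
        raise ValueError("max_lag_s must be below half the signal duration")
    if lag_step_s is None:
        step = 1
    else:
        step = int(round(lag_step_s / dt))
        if step < 1 or abs(step * dt - lag_step_s) > 1e-9 * dt:
            raise ValueError("lag_step_s must be a positive multiple of the sampling interval")
    max_k = int(np.floor(max_lag_s / dt / step)) * step
    ks = np.arange(-max_k, max_k + 1, step)

    min_overlap = min(MIN_OVERLAP, n)  # never exclude the full-overlap lag
    coeffs = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        if len(a) < max(2, min_overlap):
            continue
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            continue
        coeffs[i] = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    return Correlogram(
        pair=pair,
        lag_step_s=step * dt,
        lags_s=ks * dt,
        coefficients=coeffs,
    )


def _extrema(cg: Correlogram, prominence: float = PEAK_PROMINENCE):
    """Indices of local maxima and minima with the required prominence.

    Returns (max_idx, min_idx) into cg.lags_s.  NaN lags are treated as
    flat gaps (excluded).
    """
    c = np.nan_to_num(cg.coefficients, nan=0.0)
    max_idx, _ = _sig.find_peaks(c, prominence=prominence, wlen=None)
    min_idx, _ = _sig.find_peaks(-c, prominence=prominence, wlen=None)
    valid = ~np.isnan(cg.coefficients)
    max_idx = max_idx[valid[max_idx]]
    min_idx = min_idx[valid[min_idx]]
    return max_idx, min_idx


def ptcc(
    cg: Correlogram,
    window_s: float = PTCC_WINDOW_S,
    mode: str = "signed",
) -> tuple[float | None, list[str]]:
    """Peak-to-trough correlation coefficient of a correlogram.

    signed mode (default): value = C(e0) - C(e1) where e0 is the extremum
    nearest lag 0 and e1 the first subsequent extremum of the opposite
    kind within ``window_s`` of positive lag.  Positive for in-phase
    pairs, negative for anti-phase pairs, |value| <= 2.

    literal mode: max of the first positive-lag peak minus the minimum of
    C over [0, window_s]; always >= 0.

    Returns (value, flags); value is None with a "no-peak-found" flag if
    no qualifying extrema exist.
    """
    max_idx, min_idx = _extrema(cg)
    lags = cg.lags_s
    c = cg.coefficients

    if mode == "literal":
        pos = max_idx[(lags[max_idx] > 0) & (lags[max_idx] <= window_s)]
        if len(pos) == 0:
            return None, ["no-peak-found"]
        first_peak = c[pos[np.argmin(lags[pos])]]
        in_win = (lags >= 0) & (lags <= window_s) & ~np.isnan(c)
        if not in_win.any():
            return None, ["no-peak-found"]
        return float(first_peak - np.nanmin(c[in_win])), []

    if mode != "signed":
        raise ValueError("mode must be 'signed' or 'literal'")

    all_ext = np.concatenate(
        [np.stack([max_idx, np.ones_like(max_idx)], axis=1),
         np.stack([min_idx, -np.ones_like(min_idx)], axis=1)]
    ) if len(max_idx) + len(min_idx) else np.empty((0, 2), dtype=int)
    if len(all_ext) == 0:
        return None, ["no-peak-found"]
    # extremum nearest lag 0; ties broken toward the smaller |lag| then peak
    order = np.lexsort((-all_ext[:, 1], np.abs(lags[all_ext[:, 0]])))
    e0_idx, e0_kind = all_ext[order[0]]
    # first subsequent opposite-kind extremum within the positive-lag window
    opp = min_idx if e0_kind == 1 else max_idx
    later = opp[(lags[opp] > lags[e0_idx]) & (lags[opp] <= window_s)]
    if len(later) == 0:
        return None, ["no-peak-found"]
    e1_idx = later[np.argmin(lags[later])]
    return float(c[e0_idx] - c[e1_idx]), []


def cycle_period(
    acg: Correlogram, prominence: float = PEAK_PROMINENCE
) -> tuple[float | None, list[str]]:
    """Cycle period from an autocorrelogram.

    T is the lag of the first local maximum after lag 0 that clears the
    prominence threshold.  Returns (T_seconds, flags); (None,
    ["weak-rhythm"]) when no secondary peak exists.
    """
    max_idx, _ = _extrema(acg, prominence)
    pos = max_idx[acg.lags_s[max_idx] > acg.lag_step_s / 2]
    if len(pos) == 0:
        return None, ["weak-rhythm"]
    return float(acg.lags_s[pos[np.argmin(acg.lags_s[pos])]]), []


def phase_lag(
    ccg: Correlogram,
    cycle_period_s: float,
    mode: str = "peak_lag",
) -> tuple[float | None, list[str]]:
    """Phase lag of a channel pair from its cross-correlogram.

    peak_lag mode (default): locate the trough nearest lag 0 within
    [-T, +T], then the first peak at a greater lag; the phase is that
    peak's lag modulo T, divided by T -> [0, 1).  Synchronous pairs give
    ~0, alternating pairs ~0.5.

    literal mode: the trough-to-peak lag distance divided by T.
    """
    if cycle_period_s is None or not cycle_period_s > 0:
        return None, ["indeterminate"]
    T = cycle_period_s
    max_idx, min_idx = _extrema(ccg)
    lags = ccg.lags_s

    in_win = min_idx[np.abs(lags[min_idx]) <= T]
    if len(in_win) == 0:
        return None, ["indeterminate"]
    trough = in_win[np.argmin(np.abs(lags[in_win]))]  # trough nearest lag 0
    after = max_idx[lags[max_idx] > lags[trough]]
    if len(after) == 0:
        return None, ["indeterminate"]
    peak = after[np.argmin(lags[after])]

    if mode == "literal":
        return float((lags[peak] - lags[trough]) / T), []
    if mode != "peak_lag":
        raise ValueError("mode must be 'peak_lag' or 'literal'")
    return float((lags[peak] / T) % 1.0), []


def classify_coordination(
    metrics: RhythmMetrics,
    phase_band: float = 0.25,
    min_abs_ptcc: float = 0.3,
) -> str:
    """Label a pair synchronous, alternating or indeterminate.

    Synchronous: stable rhythm (|PTCC| >= min_abs_ptcc) with phase near 0
    (or, equivalently, near 1); alternating: stable rhythm with phase near
    0.5; otherwise indeterminate.
    """
    p, phi = metrics.ptcc, metrics.phase_lag_cycles
    if p is None or phi is None:
        return "indeterminate"
    if abs(p) < min_abs_ptcc:
        return "indeterminate"
    if phi < phase_band or phi > 1.0 - phase_band:
        return "synchronous"
    if abs(phi - 0.5) < phase_band:
        return "alternating"
    return "indeterminate"


def analyze_pair(
    x: np.ndarray,
    y: np.ndarray,
    sample_rate_hz: float,
    pair: tuple[str, str] = ("x", "y"),
    max_lag_s: float | None = None,
    lag_step_s: float | None = None,
    ptcc_mode: str = "signed",
    phase_mode: str = "peak_lag",
) -> RhythmMetrics:
    """Full rhythm analysis of one processed channel pair.

    The cycle period comes from the first channel's autocorrelogram, the
    PTCC and phase lag from the cross-correlogram.
    """
    n = len(x)
    dur = n / sample_rate_hz
    if max_lag_s is None:
        max_lag_s = min(0.45 * dur, max(PTCC_WINDOW_S, 12.0))
    acg = correlogram(x, x, sample_rate_hz, max_lag_s, lag_step_s, pair=(pair[0], pair[0]))
    ccg = correlogram(x, y, sample_rate_hz, max_lag_s, lag_step_s, pair=pair)

    m = RhythmMetrics(pair=pair)
    T, tflags = cycle_period(acg)
    m.cycle_period_s = T
    m.flags += tflags
    # For slow rhythms the 75-lag default window cannot reach the first
    # opposite extremum (at ~T/2), so the composite analysis widens the
    # stability window with the measured period.
    win = PTCC_WINDOW_S if T is None else max(PTCC_WINDOW_S, 0.75 * T)
    p, pflags = ptcc(ccg, window_s=win, mode=ptcc_mode)
    m.ptcc = p
    m.flags += pflags
    if T is not None:
        phi, fflags = phase_lag(ccg, T, mode=phase_mode)
        m.phase_lag_cycles = phi
        m.flags += fflags
    m.coordination = classify_coordination(m)
    return m
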