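"""Synthetic neurogram and footprint generators with known ground truth.

Fictive-locomotion recordings are episodic: each lumbar ventral root (or
EMG channel) fires one burst of multi-unit activity per locomotor cycle,
with left-right homologous roots either alternating (phase offset 0.5,
the normal gait) or synchronous (offset 0, a hopping gait), and ipsilateral
flexor-related (L2) vs extensor-related (L5) roots alternating.  The
generator emulates that structure — a burst envelope at a configurable
cycle period, duty cycle and per-channel phase offset, filled with a
rectifiable broadband carrier and corrupted by baseline noise — and
returns the exact envelope timing as ground truth, so every downstream
estimator can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sigprep import TimeSeriesRecording

__all__ = [
    "NeurogramSimConfig",
    "GroundTruth",
    "FootprintSimConfig",
    "FootprintRun",
    "simulate_neurogram",
    "simulate_footprints",
]


class ConfigError(ValueError):
    """Raised when a simulation config field is invalid."""


@dataclass(frozen=True)
class NeurogramSimConfig:
    """Parameters of a synthetic multi-channel neurogram.

    Attributes
    ----------
    duration_s : total recording length in seconds.
    sample_rate_hz : sampling rate; default 2500 Hz (typical for digitized
        ventral-root recordings).
    channels : ordered channel labels, e.g. ("lL2", "rL2", "lL5", "rL5").
    cycle_period_s : mean locomotor cycle period T in seconds.
    phase_offset_cycles : per-channel burst-onset offset as a fraction of
        the cycle, relative to the first channel; each in [0, 1).
    burst_duty : fraction of the cycle occupied by the burst, in (0, 1).
    burst_shape : "rectangular" or "raised_cosine" envelope.
    burst_amplitude : per-channel envelope amplitude (arbitrary units).
    carrier_noise_sd : SD of the zero-mean broadband carrier whose absolute
        value fills the burst (mimics rectifiable population activity).
        When 0 the carrier is the constant 1, so the output is the
        deterministic noise-free envelope.
    baseline_noise_sd : SD of additive zero-mean Gaussian baseline noise.
    period_jitter_cv : coefficient of variation of the per-cycle period
        (multiplicative lognormal jitter; 0 = perfectly regular rhythm).
    seed : RNG seed; identical config + seed is bit-reproducible.
    """

    duration_s: float = 60.0
    sample_rate_hz: float = 2500.0
    channels: tuple[str, ...] = ("lL2", "rL2")
    cycle_period_s: float = 5.0
    phase_offset_cycles: tuple[float, ...] = (0.0, 0.5)
    burst_duty: float = 0.5
    burst_shape: str = "rectangular"
    burst_amplitude: tuple[float, ...] | float = 1.0
    carrier_noise_sd: float = 1.0
    baseline_noise_sd: float = 0.0
    period_jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigError("duration_s must be > 0")
        if not self.sample_rate_hz > 0:
            raise ConfigError("sample_rate_hz must be > 0")
        if len(self.channels) == 0:
            raise ConfigError("channels must be non-empty")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigError("channels must be unique")
        if not self.cycle_period_s > 0:
            raise ConfigError("cycle_period_s must be > 0")
        if len(self.phase_offset_cycles) != len(self.channels):
            raise ConfigError("phase_offset_cycles must match channels in length")
        if any(not (0.0 <= p < 1.0) for p in self.phase_offset_cycles):
            raise ConfigError("phase_offset_cycles entries must lie in [0, 1)")
        if not (0.0 < self.burst_duty < 1.0):
            raise ConfigError("burst_duty must lie in (0, 1)")
        if self.burst_shape not in ("rectangular", "raised_cosine"):
            raise ConfigError("burst_shape must be 'rectangular' or 'raised_cosine'")
        if self.carrier_noise_sd < 0:
            raise ConfigError("carrier_noise_sd must be >= 0")
        if self.baseline_noise_sd < 0:
            raise ConfigError("baseline_noise_sd must be >= 0")
        if self.period_jitter_cv < 0:
            raise ConfigError("period_jitter_cv must be >= 0")

    @property
    def amplitudes(self) -> tuple[float, ...]:
        a = self.burst_amplitude
        if isinstance(a, (int, float)):
            return tuple(float(a) for _ in self.channels)
        if len(a) != len(self.channels):
            raise ConfigError("burst_amplitude must be scalar or match channels")
        return tuple(float(v) for v in a)


@dataclass
class GroundTruth:
    """Exact envelope timing of a simulated neurogram.

    ``cycle_periods_s`` holds the realized (possibly jittered) period of
    every cycle; ``onsets_s``/``offsets_s`` map channel label to the burst
    boundaries that fall inside the recording.
    """

    cycle_periods_s: np.ndarray
    phase_offset_cycles: dict[str, float]
    onsets_s: dict[str, np.ndarray]
    offsets_s: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for ch, on in self.onsets_s.items():
            off = self.offsets_s[ch]
            if len(on) > 1 and not np.all(np.diff(on) > 0):
                raise ValueError(f"onsets for {ch} must be strictly increasing")
            if np.any(off[: len(on)] <= on[: len(off)]):
                raise ValueError(f"offsets for {ch} must exceed onsets")


def _cycle_starts(cfg: NeurogramSimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Realized cycle start times and periods covering the recording."""
    T = cfg.cycle_period_s
    n = int(math.ceil(cfg.duration_s / T)) + 3
    if cfg.period_jitter_cv > 0:
        # lognormal with mean 1 and the requested CV
        sigma = math.sqrt(math.log(1.0 + cfg.period_jitter_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        factors = np.ones(n)
    periods = T * factors
    while periods.sum() < cfg.duration_s + T:
        extra = T * (rng.lognormal(-0.5 * sigma**2, sigma) if cfg.period_jitter_cv > 0 else 1.0)
        periods = np.append(periods, extra)
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    return starts, periods


def simulate_neurogram(config: NeurogramSimConfig) -> tuple[TimeSeriesRecording, GroundTruth]:
    """Generate a synthetic neurogram and its exact ground truth.

    Per channel the signal is ``amplitude * envelope * |carrier| + baseline``
    where the envelope bursts start at the (jittered) cycle boundaries
    shifted by the channel's phase offset.  Identical config + seed
    regenerates bit-identical samples.
    """
    rng = np.random.default_rng(config.seed)
    starts, periods = _cycle_starts(config, rng)
    fs = config.sample_rate_hz
    n_samples = int(round(config.duration_s * fs))
    t = np.arange(n_samples) / fs

    amps = config.amplitudes
    traces = np.empty((len(config.channels), n_samples))
    onsets: dict[str, np.ndarray] = {}
    offsets: dict[str, np.ndarray] = {}

    for ci, ch in enumerate(config.channels):
        off = config.phase_offset_cycles[ci]
        ch_on = starts + off * periods
        ch_off = ch_on + config.burst_duty * periods
        env = np.zeros(n_samples)
        for a, b in zip(ch_on, ch_off):
            i0 = max(0, int(math.ceil(a * fs)))
            i1 = min(n_samples, int(math.ceil(b * fs)))
            if i1 <= i0:
                continue
            if config.burst_shape == "rectangular":
                env[i0:i1] = 1.0
            else:
                u = (t[i0:i1] - a) / (b - a)
                env[i0:i1] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        if config.carrier_noise_sd > 0:
            carrier = np.abs(rng.normal(0.0, config.carrier_noise_sd, n_samples))
        else:
            carrier = 1.0
        sig = amps[ci] * env * carrier
        if config.baseline_noise_sd > 0:
            sig = sig + rng.normal(0.0, config.baseline_noise_sd, n_samples)
        traces[ci] = sig
        keep = (ch_on >= 0) & (ch_on < config.duration_s)
        onsets[ch] = ch_on[keep]
        offsets[ch] = ch_off[keep]

    rec = TimeSeriesRecording(
        sample_rate_hz=fs, channel_labels=list(config.channels), samples=traces
    )
    truth = GroundTruth(
        cycle_periods_s=periods,
        phase_offset_cycles=dict(zip(config.channels, config.phase_offset_cycles)),
        onsets_s=onsets,
        offsets_s=offsets,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Footprints


@dataclass(frozen=True)
class FootprintSimConfig:
    """Parameters of a synthetic painted-paw footprint run.

    Emulates a run along a straight track: the right hind paw prints at
    multiples of the stride length; the left hind paw at a configurable
    phase of the right stride (0.5 = alternating walk, 0 = hopping);
    forelimbs likewise with their own offset.  Placement noise is
    isotropic Gaussian in centimetres.
    """

    n_strides: int = 10
    stride_length_cm: float = 6.0
    hind_phase_offset_cycles: float = 0.5
    fore_phase_offset_cycles: float = 0.5
    lateral_spacing_cm: float = 2.0
    placement_noise_sd_cm: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ConfigError("n_strides must be >= 2")
        if not self.stride_length_cm > 0:
            raise ConfigError("stride_length_cm must be > 0")
        for name in ("hind_phase_offset_cycles", "fore_phase_offset_cycles"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.placement_noise_sd_cm < 0:
            raise ConfigError("placement_noise_sd_cm must be >= 0")


@dataclass
class FootprintRun:
    """Ordered paw prints of one run: DataFrame with paw, x_cm, y_cm."""

    run_id: str
    prints: pd.DataFrame  # columns: step_index, paw, x_cm, y_cm

    PAWS = ("LF", "RF", "LH", "RH")

    def paw_x(self, paw: str) -> np.ndarray:
        sel = self.prints.loc[self.prints["paw"] == paw, "x_cm"]
        return np.sort(sel.to_numpy(dtype=float))


def simulate_footprints(
    config: FootprintSimConfig, run_id: str = "sim"
) -> tuple[FootprintRun, dict]:
    """Generate a footprint run and a truth record of the ideal geometry."""
    rng = np.random.default_rng(config.seed)
    k = np.arange(config.n_strides, dtype=float)
    s = config.stride_length_cm
    half = config.lateral_spacing_cm / 2.0

    ideal = {
        "RH": (k * s, -half),
        "LH": ((k + config.hind_phase_offset_cycles) * s, half),
        "RF": (k * s + 0.5 * s, -half),
        "LF": ((k + config.fore_phase_offset_cycles) * s + 0.5 * s, half),
    }
    rows = []
    for paw in ("LF", "RF", "LH", "RH"):
        x0, y0 = ideal[paw]
        noise_x = rng.normal(0.0, config.placement_noise_sd_cm, len(x0)) if config.placement_noise_sd_cm > 0 else 0.0
        noise_y = rng.normal(0.0, config.placement_noise_sd_cm, len(x0)) if config.placement_noise_sd_cm > 0 else 0.0
        x = x0 + noise_x
        y = np.full(len(x0), y0) + noise_y
        for i in range(len(x0)):
            rows.append({"step_index": i, "paw": paw, "x_cm": x[i], "y_cm": y[i]})
    prints = pd.DataFrame(rows).sort_values(["paw", "step_index"]).reset_index(drop=True)
    truth = {
        "stride_length_cm": s,
        "hind_phase_offset_cycles": config.hind_phase_offset_cycles,
        "fore_phase_offset_cycles": config.fore_phase_offset_cycles,
        "ideal_x_cm": {p: ideal[p][0].tolist() for p in ideal},
    }
    return FootprintRun(run_id=run_id, prints=prints), truth
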