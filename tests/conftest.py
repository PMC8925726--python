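import pytest

from locorhythm import NeurogramSimConfig, simulate_neurogram


def snr_config(**kw) -> NeurogramSimConfig:
    """Bursting config at carrier SNR 5 (amplitude*carrier_sd / baseline_sd)."""
    defaults = dict(
        duration_s=60.0,
        channels=("lL2", "rL2"),
        phase_offset_cycles=(0.0, 0.5),
        cycle_period_s=5.0,
        burst_duty=0.5,
        carrier_noise_sd=1.0,
        baseline_noise_sd=0.2,
        seed=0,
    )
    defaults.update(kw)
    return NeurogramSimConfig(**defaults)


@pytest.fixture
def antiphase_pair():
    """60-s two-channel simulation with left-right alternation at SNR 5."""
    cfg = snr_config(seed=11)
    rec, truth = simulate_neurogram(cfg)
    return cfg, rec, truth


@pytest.fixture
def sync_pair():
    """60-s two-channel synchronous simulation at SNR 5."""
    cfg = snr_config(phase_offset_cycles=(0.0, 0.0), seed=12)
    rec, truth = simulate_neurogram(cfg)
    return cfg, rec, truth


def circ_err(a: float, b: float) -> float:
    """Circular distance between two phases in [0, 1)."""
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)
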