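"""Burst detection and circular statistics of burst-onset phases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from locorhythm import (
    BurstTrain,
    burst_duration_summary,
    burst_phases,
    circular_summary,
    detect_bursts,
    preprocess,
    rayleigh_test,
    simulate_neurogram,
)
from locorhythm.bursts import rayleigh_p

from conftest import circ_err, snr_config


def test_detect_on_noise_free_envelope_hits_truth_onsets():
    cfg = snr_config(carrier_noise_sd=0.0, baseline_noise_sd=0.0,
                     sample_rate_hz=500.0, seed=0)
    rec, truth = simulate_neurogram(cfg)
    train = detect_bursts(rec.samples[0], 500.0, channel="lL2")
    true_on = truth.onsets_s["lL2"]
    assert len(train) == len(true_on)
    np.testing.assert_allclose(train.onsets_s, true_on, atol=1.0 / 500.0 + 1e-12)


def test_detect_all_zero_trace_is_empty():
    train = detect_bursts(np.zeros(1000), 100.0)
    assert len(train) == 0


def test_detect_matches_truth_at_snr5():
    cfg = snr_config(duration_s=60.0, seed=8)  # 12 cycles at T = 5 s
    rec, truth = simulate_neurogram(cfg)
    seg = preprocess(rec)
    train = detect_bursts(seg.channel("lL2"), 100.0, channel="lL2")
    true_on = truth.onsets_s["lL2"]
    matched = sum(np.min(np.abs(train.onsets_s - t)) <= 0.05 for t in true_on)
    assert matched / len(true_on) >= 0.9


def test_burst_phases_self_and_antiphase():
    ref = BurstTrain("r", np.arange(0.0, 50.0, 5.0), np.arange(0.0, 50.0, 5.0) + 2.0)
    assert np.allclose(burst_phases(ref, ref), 0.0)
    tgt = BurstTrain("t", np.arange(2.5, 50.0, 5.0), np.arange(2.5, 50.0, 5.0) + 2.0)
    phases = burst_phases(ref, tgt)
    assert np.allclose(phases, 0.5)
    with pytest.raises(ValueError):
        burst_phases(BurstTrain("r", np.array([1.0]), np.array([2.0])), tgt)


def test_burst_phases_jittered_simulation_mean_half():
    cfg = snr_config(duration_s=120.0, period_jitter_cv=0.05, seed=9)
    rec, _ = simulate_neurogram(cfg)
    seg = preprocess(rec)
    ta = detect_bursts(seg.channel("lL2"), 100.0, channel="lL2")
    tb = detect_bursts(seg.channel("rL2"), 100.0, channel="rL2")
    cs = circular_summary(burst_phases(ta, tb))
    assert circ_err(cs.mean_phase, 0.5) <= 0.05
    assert cs.rayleigh_p < 0.05


def test_circular_summary_examples():
    cs = circular_summary(np.array([0.1, 0.1, 0.1]))
    assert cs.resultant_length == pytest.approx(1.0)
    assert cs.mean_phase == pytest.approx(0.1)

    cs = circular_summary(np.array([0.0, 0.25, 0.5, 0.75]))
    assert cs.resultant_length == pytest.approx(0.0, abs=1e-12)

    # hand vector sum: (1,0) + (0,1) -> |mean| = sqrt(2)/2, angle 45 deg
    cs = circular_summary(np.array([0.0, 0.25]))
    assert cs.resultant_length == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
    assert cs.mean_phase == pytest.approx(0.125)

    with pytest.raises(ValueError):
        circular_summary(np.array([]))


def test_rayleigh_null_and_concentrated():
    assert rayleigh_p(10, 0.0) == pytest.approx(1.0, abs=0.01)
    cs = circular_summary(np.full(10, 0.3))
    assert rayleigh_test(cs) < 1e-3
    # Monte-Carlo route agrees on the concentrated case
    assert rayleigh_test(cs, method="mc", n_mc=2000, seed=0) < 5e-3


def test_rayleigh_agrees_with_pingouin():
    # pingouin uses the Wilkie (1983) approximation; the second-order
    # series used here agrees with it to ~1e-3 at moderate n, and the
    # Z statistic must match exactly
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(10)
    for _ in range(5):
        phases = rng.uniform(size=15)
        cs = circular_summary(phases)
        z_ref, p_ref = pingouin.circ_rayleigh(2 * np.pi * phases)
        assert cs.rayleigh_z == pytest.approx(z_ref, abs=1e-9)
        assert cs.rayleigh_p == pytest.approx(p_ref, abs=2e-3)


def test_rayleigh_monotone_in_resultant_length():
    ps = [rayleigh_p(20, r) for r in np.linspace(0, 0.9, 10)]
    assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=0.999), min_size=2,
                max_size=30),
       st.floats(min_value=0.0, max_value=1.0))
def test_circular_mean_rotation_invariance(phases, rot):
    """Rotating all phases by a constant rotates the mean by the same."""
    base = circular_summary(np.array(phases))
    moved = circular_summary((np.array(phases) + rot) % 1.0)
    assert moved.resultant_length == pytest.approx(base.resultant_length,
                                                  abs=1e-9)
    if base.resultant_length > 1e-6:
        assert circ_err(moved.mean_phase, (base.mean_phase + rot) % 1.0) < 1e-6


def test_burst_duration_summary():
    a = BurstTrain("a", np.array([0.0, 5.0]), np.array([1.5, 6.5]))
    assert burst_duration_summary(a, a)["ratio_b_over_a"] == pytest.approx(1.0)

    cfg_a = snr_config(channels=("x",), phase_offset_cycles=(0.0,),
                       burst_duty=0.3, carrier_noise_sd=0.0,
                       baseline_noise_sd=0.0, sample_rate_hz=500.0)
    cfg_b = snr_config(channels=("x",), phase_offset_cycles=(0.0,),
                       burst_duty=0.6, carrier_noise_sd=0.0,
                       baseline_noise_sd=0.0, sample_rate_hz=500.0)
    ta = detect_bursts(simulate_neurogram(cfg_a)[0].samples[0], 500.0)
    tb = detect_bursts(simulate_neurogram(cfg_b)[0].samples[0], 500.0)
    ratio = burst_duration_summary(ta, tb)["ratio_b_over_a"]
    assert ratio == pytest.approx(2.0, abs=0.1)

    single_a = BurstTrain("a", np.array([0.0]), np.array([1.0]))
    single_b = BurstTrain("b", np.array([0.0]), np.array([2.0]))
    assert burst_duration_summary(single_a, single_b)["ratio_b_over_a"] == 2.0
    with pytest.raises(ValueError):
        burst_duration_summary(single_a, BurstTrain("b", np.array([]), np.array([])))


def test_detection_estimation_consistency():
    """Median onset interval agrees with the correlogram cycle period."""
    from locorhythm import analyze_pair

    cfg = snr_config(seed=14)
    rec, _ = simulate_neurogram(cfg)
    seg = preprocess(rec)
    train = detect_bursts(seg.channel("lL2"), 100.0)
    med_T = float(np.median(np.diff(train.onsets_s)))
    m = analyze_pair(seg.samples[0], seg.samples[1], 100.0, lag_step_s=0.01)
    assert med_T == pytest.approx(m.cycle_period_s, rel=0.05)
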