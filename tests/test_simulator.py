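"""Synthetic recording generator: determinism, noise closure, ground truth."""
import numpy as np
import pytest

from poretrap import (NoiseSpec, VoltageProtocol, get_preset,
                      open_pore_current, simulate_recording,
                      synth_colored_noise, segment_event, lowpass_filter,
                      split_cycles)
from poretrap.simulate import SimPreset


def test_same_seed_bit_identical(reference_pore):
    proto = VoltageProtocol([(300.0, 0.5), (-300.0, 0.2)], n_cycles=3)
    t1, g1 = simulate_recording(proto, reference_pore, get_preset("biotin"),
                                seed=9, fs=20_000.0)
    t2, g2 = simulate_recording(proto, reference_pore, get_preset("biotin"),
                                seed=9, fs=20_000.0)
    np.testing.assert_array_equal(t1.samples, t2.samples)
    assert g1.to_dict() == g2.to_dict()


def test_white_only_variance():
    x = synth_colored_noise(1_000_000, 200_000.0,
                            NoiseSpec(white_sd=0.08, flicker_amp=0.0), seed=1)
    assert x.var() == pytest.approx(0.08 ** 2, rel=0.05)
    assert abs(x.mean()) < 1e-3


def test_colored_noise_deterministic():
    spec = NoiseSpec(white_sd=0.05, flicker_amp=1e-3)
    a = synth_colored_noise(10_000, 10_000.0, spec, seed=3)
    b = synth_colored_noise(10_000, 10_000.0, spec, seed=3)
    np.testing.assert_array_equal(a, b)


def test_noiseless_eventless_trace_is_piecewise_constant(reference_pore):
    proto = VoltageProtocol([(300.0, 0.2), (-300.0, 0.1)], n_cycles=2)
    preset = SimPreset(name="custom", depth_levels=[0.5], level_weights=[1.0],
                       switch_rate=0.0, capture_rate=0.0,
                       event_stability="none")
    trace, truth = simulate_recording(
        proto, reference_pore, preset,
        noise=NoiseSpec(white_sd=0.0, flicker_amp=0.0), seed=0, fs=10_000.0)
    i0 = open_pore_current(reference_pore)
    assert truth.n_captured == 0
    levels = np.unique(trace.samples)
    np.testing.assert_allclose(sorted(levels), [-i0, i0], atol=1e-12)


def test_open_segment_rms_matches_white_sd(reference_pore):
    proto = VoltageProtocol([(300.0, 1.0), (-300.0, 0.2)], n_cycles=1)
    trace, _ = simulate_recording(
        proto, reference_pore, get_preset("sa_excess"),
        noise=NoiseSpec(white_sd=0.08, flicker_amp=0.0), seed=4, fs=50_000.0)
    rms = trace.samples[:50_000].std()
    assert rms == pytest.approx(0.08, rel=0.10)


def test_every_capture_found_at_annotated_time(reference_pore):
    """With a high capture rate every cycle traps, and segmentation finds
    each gated onset within 5 ms of the annotated capture time."""
    fs = 50_000.0
    proto = VoltageProtocol([(300.0, 1.2), (-300.0, 0.3)], n_cycles=20)
    trace, truth = simulate_recording(proto, reference_pore,
                                      get_preset("amine"), seed=6, fs=fs,
                                      capture_delay_s=0.3)
    assert truth.n_captured == 20
    filtered = lowpass_filter(trace, 20_000.0)
    spans = split_cycles(filtered, proto)
    proto1 = VoltageProtocol(proto.phases, n_cycles=1)
    for ci, (a, b) in enumerate(spans):
        ev = segment_event(filtered.slice(a, b), proto1, cycle_index=ci)
        assert ev.valid, f"cycle {ci} missed"
        onset_abs = a + ev.gated_span[0]
        assert abs(onset_abs - truth.capture_index[ci]) <= 0.005 * fs


def test_ground_truth_spans_consistent(reference_pore):
    proto = VoltageProtocol([(300.0, 0.5), (-300.0, 0.1)], n_cycles=4)
    trace, truth = simulate_recording(proto, reference_pore,
                                      get_preset("tween"), seed=7,
                                      fs=20_000.0)
    assert len(truth.cycle_spans) == 4
    for cyc_gated, (c0, c1) in zip(truth.gated_spans, truth.cycle_spans):
        for s0, s1 in cyc_gated:
            assert c0 <= s0 < s1 <= c1
    # annotated gated levels really sit below baseline in the emitted trace
    i0 = open_pore_current(reference_pore)
    for pieces in truth.level_pieces:
        for s0, s1, depth in pieces:
            if s1 - s0 > 50:
                seg = trace.samples[s0:s1]
                assert seg.mean() < i0 * 0.97


class TestPresets:
    def test_amine_is_single_shallow_stable(self):
        p = get_preset("amine")
        assert list(p.depth_levels) == [0.10]
        assert p.event_stability == "persistent"

    def test_biotin_has_three_discrete_levels(self):
        p = get_preset("biotin")
        assert len(p.depth_levels) == 3
        assert 0.2 <= min(p.depth_levels) and max(p.depth_levels) <= 0.7

    def test_tween_discrete_has_four_levels(self):
        assert len(get_preset("tween").depth_levels) == 4

    def test_sa_excess_never_traps(self):
        p = get_preset("sa_excess")
        assert p.capture_rate == 0.0
        assert p.event_stability == "none"

    def test_unknown_preset_lists_registry(self):
        with pytest.raises(KeyError, match="amine"):
            get_preset("nope")

    def test_preset_params_serialized_with_truth(self, reference_pore):
        proto = VoltageProtocol([(300.0, 0.2), (-300.0, 0.1)], n_cycles=1)
        _, truth = simulate_recording(proto, reference_pore,
                                      get_preset("amine"), seed=1,
                                      fs=10_000.0)
        assert truth.preset_params["name"] == "amine"
        assert truth.preset_name == "amine"

    def test_mutating_a_copy_leaves_registry_untouched(self):
        p = get_preset("amine")
        p.capture_rate = 0.0
        assert get_preset("amine").capture_rate > 0


def test_protocol_without_trap_phase_rejected(reference_pore):
    with pytest.raises(ValueError):
        VoltageProtocol([(-300.0, 0.5)], n_cycles=1)
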