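"""Breath segmentation, ventilation metrics and behavioral-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capnotrace.pipeline import _drop_in_movement
from capnotrace.plethysmography import (
    BreathTable,
    PlethysmographyTrace,
    compute_ventilation,
    detect_active_expiration,
    detect_breaths,
    detect_sniff_bouts,
    movement_sonogram,
)
from capnotrace.synthetic import SimulationConfig, simulate_breathing


def _sinusoid_trace(freq_hz=4.0, duration_s=10.0, fs=200.0, amp=1.0, offset=0.0):
    t = np.arange(0, duration_s, 1 / fs)
    return PlethysmographyTrace(amp * np.sin(2 * np.pi * freq_hz * t) + offset, fs)


def test_pure_sinusoid_breath_count_and_rate():
    br = detect_breaths(_sinusoid_trace())
    assert len(br) == 40
    assert np.median(br.fr_inst) == pytest.approx(240.0, rel=0.02)


def test_flat_and_zero_traces_give_empty_tables():
    flat = PlethysmographyTrace(np.full(2000, 3.7), 200.0)
    assert len(detect_breaths(flat)) == 0
    zero = PlethysmographyTrace(np.zeros(2000), 200.0)
    assert len(detect_breaths(zero)) == 0


@settings(max_examples=20, deadline=None)
@given(scale=st.floats(0.2, 50.0), offset=st.floats(-10.0, 10.0))
def test_breath_count_invariant_under_gain_and_offset(scale, offset):
    base = _sinusoid_trace()
    scaled = PlethysmographyTrace(scale * base.samples + offset, base.rate)
    assert len(detect_breaths(scaled)) == len(detect_breaths(base))


def test_breath_recall_and_precision_on_generator(breathing_session):
    """>= 95% of true breaths recovered, >= 95% of detections genuine,
    judged outside movement bouts (artefactual excursions are not breaths)."""
    _, wbp, _, truth = breathing_session
    br = detect_breaths(wbp)
    move = list(zip(truth.movement_onsets_s, truth.movement_durations_s))

    def outside_movement(times):
        keep = np.ones(times.size, dtype=bool)
        for on, du in move:
            keep &= ~((times >= on - 0.3) & (times < on + du + 0.3))
        return keep

    det = br.onset_s[outside_movement(br.onset_s)]
    tru = truth.breath_onsets_s[outside_movement(truth.breath_onsets_s)]
    half_cycle = np.median(np.diff(tru)) / 2
    d_tru = np.array([np.min(np.abs(det - t)) for t in tru])
    d_det = np.array([np.min(np.abs(tru - t)) for t in det])
    assert np.mean(d_tru <= half_cycle) >= 0.95          # recall
    assert np.mean(d_det <= half_cycle) >= 0.95          # precision


def test_ventilation_identity_and_constant_product():
    n = 100
    br = BreathTable(
        onset_s=np.arange(n) * 0.5,
        peak_s=np.arange(n) * 0.5 + 0.1,
        peak_value=np.full(n, 0.16),
        trough_s=np.arange(n) * 0.5 + 0.3,
        trough_value=np.full(n, -0.09),
        vt=np.full(n, 0.25),
        cycle_s=np.full(n, 0.5),
        trough_depth=np.full(n, 0.09),
    )
    vent = compute_ventilation(br, window_s=10.0)
    np.testing.assert_array_equal(vent.ve, vent.vt * vent.fr)
    assert np.allclose(vent.vt, 0.25)
    assert np.allclose(vent.fr, 120.0)
    assert np.allclose(vent.ve, 30.0)


def test_ventilation_scales_with_pressure(breathing_session):
    _, wbp, _, _ = breathing_session
    br1 = detect_breaths(wbp)
    doubled = PlethysmographyTrace(
        2 * wbp.samples, wbp.rate, wbp.body_mass_g, wbp.calibration_ml_per_unit
    )
    br2 = detect_breaths(doubled)
    v1 = compute_ventilation(br1, window_s=10.0)
    v2 = compute_ventilation(br2, window_s=10.0)
    m = min(v1.time_s.size, v2.time_s.size)
    assert np.nanmedian(v2.vt[:m] / v1.vt[:m]) == pytest.approx(2.0, rel=0.02)
    assert np.nanmedian(v2.fr[:m] / v1.fr[:m]) == pytest.approx(1.0, rel=0.02)
    assert np.nanmedian(v2.ve[:m] / v1.ve[:m]) == pytest.approx(2.0, rel=0.02)


def test_ventilation_input_validation():
    from capnotrace.plethysmography import BreathTable

    with pytest.raises(ValueError):
        compute_ventilation(BreathTable.empty())
    n = 10
    br = BreathTable(
        onset_s=np.arange(n) * 2.0, peak_s=np.arange(n) * 2.0 + 0.5,
        peak_value=np.ones(n), trough_s=np.arange(n) * 2.0 + 1.2,
        trough_value=-np.ones(n), vt=np.ones(n), cycle_s=np.full(n, 2.0),
        trough_depth=np.ones(n),
    )
    with pytest.raises(ValueError):
        compute_ventilation(br, window_s=1.0)   # shorter than one cycle


def test_sniff_bouts_recovered_without_movement():
    cfg = SimulationConfig(seed=7, movement_rate_per_min=0.0)
    wbp, _, truth = simulate_breathing(cfg)
    vent = compute_ventilation(detect_breaths(wbp))
    bouts = detect_sniff_bouts(vent)
    # near-complete recovery (a bout whose realized breaths span less than
    # the minimum duration is legitimately rejected) with no false bouts
    assert len(bouts) >= truth.sniff_onsets_s.size - 1
    for on in bouts.onsets_s:
        assert np.min(np.abs(truth.sniff_onsets_s - on)) < 0.4  # within one breath


def test_sniff_threshold_degenerate_cases(breathing_session):
    _, wbp, _, _ = breathing_session
    vent = compute_ventilation(detect_breaths(wbp))
    none = detect_sniff_bouts(vent, fr_threshold=1e6)
    assert len(none) == 0
    everything = detect_sniff_bouts(vent, fr_threshold=0.0, min_duration_s=0.5)
    assert len(everything) == 1
    assert everything.durations_s[0] == pytest.approx(
        vent.breaths.onset_s[-1] + vent.breaths.cycle_s[-1] - vent.breaths.onset_s[0],
        rel=0.01,
    )


def test_detectors_monotone_in_threshold(breathing_session):
    cfg, wbp, _, _ = breathing_session
    vent = compute_ventilation(detect_breaths(wbp))
    loose = detect_sniff_bouts(vent, threshold_factor=1.8)
    strict = detect_sniff_bouts(vent, threshold_factor=2.5)
    assert len(strict) <= len(loose)
    br = detect_breaths(wbp)
    loose_e = detect_active_expiration(wbp, br, 3.0, protocol=cfg.protocol())
    strict_e = detect_active_expiration(wbp, br, 8.0, protocol=cfg.protocol())
    assert set(np.round(strict_e.onsets_s, 3)) <= set(np.round(loose_e.onsets_s, 3))


def test_active_expiration_recovers_injected_events():
    cfg = SimulationConfig(seed=9, movement_rate_per_min=0.0)
    wbp, _, truth = simulate_breathing(cfg)
    br = detect_breaths(wbp)
    ev = detect_active_expiration(wbp, br, protocol=cfg.protocol())
    assert len(ev) >= 0.9 * truth.exp_onsets_s.size
    d = np.array([np.min(np.abs(truth.exp_onsets_s - t)) for t in ev.onsets_s])
    assert np.mean(d < 0.3) >= 0.95


def test_active_expiration_degenerate_thresholds():
    br = detect_breaths(_sinusoid_trace(duration_s=20.0))
    tr = _sinusoid_trace(duration_s=20.0)
    none = detect_active_expiration(tr, br, trough_z_threshold=4.0)
    assert len(none) == 0                     # all troughs equal
    every = detect_active_expiration(tr, br, trough_z_threshold=0.0)
    assert len(every) == len(br)


def test_sonogram_silent_channel_and_errors():
    _, _, _, ev = movement_sonogram(np.zeros(4000), 100.0)
    assert len(ev) == 0
    with pytest.raises(ValueError):
        movement_sonogram(np.zeros(10), 100.0, window_s=1.0)


def test_sonogram_recovers_movement_bouts(breathing_session):
    _, wbp, movement, truth = breathing_session
    _, _, _, ev = movement_sonogram(movement, wbp.rate)

    def jaccard(onsets_a, durs_a, onsets_b, durs_b, t_end):
        grid = np.linspace(0, t_end, int(t_end * 20))
        def mask(on, du):
            m = np.zeros(grid.size, bool)
            for o, d in zip(on, du):
                m |= (grid >= o) & (grid < o + d)
            return m
        a, b = mask(onsets_a, durs_a), mask(onsets_b, durs_b)
        return np.sum(a & b) / max(np.sum(a | b), 1)

    j = jaccard(ev.onsets_s, ev.durations_s,
                truth.movement_onsets_s, truth.movement_durations_s,
                wbp.duration_s)
    assert j >= 0.8

    # the same bouts contaminate the WBP channel: sonograms cross-validate
    _, _, _, ev_wbp = movement_sonogram(wbp.samples, wbp.rate)
    matched = sum(
        np.min(np.abs(ev_wbp.onsets_s - o)) < 0.6 for o in ev.onsets_s
    )
    assert matched >= 0.8 * len(ev)


def test_movement_filtering_of_behavioral_events(breathing_session):
    cfg, wbp, movement, truth = breathing_session
    vent = compute_ventilation(detect_breaths(wbp))
    sniffs = detect_sniff_bouts(vent)
    _, _, _, mv = movement_sonogram(movement, wbp.rate)
    kept = _drop_in_movement(sniffs, mv)
    assert len(kept) <= len(sniffs)
    # every surviving bout corresponds to an injected sniff
    for on in kept.onsets_s:
        assert np.min(np.abs(truth.sniff_onsets_s - on)) < 0.5
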