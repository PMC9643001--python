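"""F/F0 conditioning, transient detection and kinetics, four-criterion QC."""

import numpy as np
import pytest
from scipy import stats as sps

from capnotrace.calcium import (
    compute_dff,
    detect_transients,
    fit_transient_kinetics,
    qc_cell,
    subtract_background,
)
from capnotrace.plethysmography import EventSeries
from capnotrace.synthetic import NeuronTemplate, SimulationConfig, _kernel, simulate_population

FS = 15.0


def _trace_from_signal(signal, times=None, f0=1000.0, baseline_end=10.0):
    t = np.arange(signal.size) / FS if times is None else times
    return compute_dff(t, f0 * (1.0 + signal), (0.0, baseline_end))


def _events_signal(times, amp=0.8, tau_r=0.2, tau_d=1.5, events=()):
    t = np.arange(0, 120, 1 / FS)
    sig = np.zeros(t.size)
    for te in events:
        sig += amp * _kernel(t - te, tau_r, tau_d)
    return t, sig


def test_dff_constant_and_gain_invariance():
    t = np.arange(0, 60, 1 / FS)
    tr = compute_dff(t, np.full(t.size, 123.0), (0.0, 10.0))
    np.testing.assert_allclose(tr.dff, 1.0)
    rng = np.random.default_rng(0)
    F = 500.0 * (1 + 0.3 * rng.random(t.size))
    a = compute_dff(t, F, (0.0, 10.0))
    b = compute_dff(t, 3.0 * F, (0.0, 10.0))
    np.testing.assert_allclose(a.dff, b.dff, rtol=1e-12)


def test_dff_input_validation():
    t = np.arange(0, 10, 1 / FS)
    with pytest.raises(ValueError):
        compute_dff(t, np.full(t.size, 5.0), (0.0, 20.0))    # window outside record
    with pytest.raises(ValueError):
        compute_dff(t, np.zeros(t.size), (0.0, 5.0))         # F0 <= 0


def test_background_subtraction_recovers_signal():
    t = np.arange(0, 120, 1 / FS)
    art = np.zeros(t.size)
    for on, amp in [(20, 0.3), (35, -0.3), (50, 0.25), (70, -0.25), (95, 0.3)]:
        sel = (t >= on) & (t < on + 1.0)
        art[sel] += amp * np.hanning(sel.sum())
    sig = 0.8 * _kernel(t - 40.0, 0.2, 1.5) + 0.6 * _kernel(t - 80.0, 0.2, 1.5)
    roi = compute_dff(t, 1000 * (1 + sig + art), (0.0, 10.0))
    bg = compute_dff(t, 700 * (1 + art), (0.0, 10.0))
    clean = compute_dff(t, 1000 * (1 + sig), (0.0, 10.0))
    corrected = subtract_background(roi, bg)
    assert corrected.meta["background_subtracted"]
    np.testing.assert_allclose(corrected.dff, clean.dff, atol=1e-2)
    # artefact power reduced at least 10-fold
    before = np.var(roi.dff - clean.dff)
    after = np.var(corrected.dff - clean.dff)
    assert before / max(after, 1e-30) >= 10.0


def test_background_identity_and_grid_mismatch():
    t, sig = _events_signal(None, events=[40.0])
    roi = _trace_from_signal(sig)
    flat_bg = _trace_from_signal(np.zeros(sig.size))
    corrected = subtract_background(roi, flat_bg)
    np.testing.assert_allclose(corrected.dff, roi.dff, atol=1e-9)
    short = compute_dff(t[:-10], 1000 * np.ones(t.size - 10), (0.0, 5.0))
    with pytest.raises(ValueError):
        subtract_background(roi, short)


def test_detect_transients_flat_noise_free():
    tr = _trace_from_signal(np.zeros(1800))
    assert detect_transients(tr) == []


def test_detect_transients_recall_on_generator(event_recall):
    cfg = SimulationConfig(seed=11)
    ds = simulate_population({"NC": 3}, cfg)
    for trace, truth in zip(ds.traces, ds.truth.neurons):
        det = [ev.onset_s for ev in detect_transients(trace)]
        assert event_recall(det, truth.event_times_s) >= 0.9


def test_close_events_merge_into_one_detection():
    _, two_near = _events_signal(None, events=[40.0, 40.6])
    near = detect_transients(_trace_from_signal(two_near))
    assert len(near) == 1
    _, two_far = _events_signal(None, events=[40.0, 60.0])
    far = detect_transients(_trace_from_signal(two_far))
    assert len(far) == 2


def test_kinetics_noise_free_within_one_percent():
    t, sig = _events_signal(None, events=[40.0], tau_d=1.5)
    tr = _trace_from_signal(sig)
    ev = fit_transient_kinetics(tr, detect_transients(tr)[0])
    assert ev.fit_converged
    assert ev.decay_tau_s == pytest.approx(1.5, rel=0.01)
    assert ev.gof > 0.999
    assert 0.1 < ev.rise_time_s < 0.5


def test_kinetics_noisy_median_error_within_ten_percent():
    rng = np.random.default_rng(3)
    taus = []
    for k in range(15):
        t, sig = _events_signal(None, events=[40.0 + rng.uniform(-5, 5)])
        tr = compute_dff(t, 1000 * (1 + sig + rng.normal(0, 0.05, t.size)), (0.0, 10.0))
        evs = detect_transients(tr)
        if not evs:
            continue
        fit = fit_transient_kinetics(tr, evs[0])
        if fit.fit_converged:
            taus.append(fit.decay_tau_s)
    assert len(taus) >= 10
    assert np.median(np.abs(np.array(taus) - 1.5) / 1.5) <= 0.10


def test_kinetics_do_not_change_across_epochs():
    """Indicator dynamics are epoch-invariant: fitted decay taus from before,
    during and after hypercapnia come from one distribution."""
    cfg = SimulationConfig(seed=13)
    ds = simulate_population({"T": 2}, cfg)
    hyper = (cfg.true_epoch_starts()[1], cfg.true_epoch_starts()[3])
    inside, outside = [], []
    for trace in ds.traces:
        for ev in detect_transients(trace):
            fit = fit_transient_kinetics(trace, ev)
            if not fit.fit_converged or fit.gof < 0.5:
                continue
            (inside if hyper[0] <= ev.onset_s < hyper[1] else outside).append(
                fit.decay_tau_s
            )
    assert len(inside) >= 8 and len(outside) >= 8
    p = sps.mannwhitneyu(inside, outside).pvalue
    assert p > 0.05


def _movement(bouts):
    on = np.array([b[0] for b in bouts])
    du = np.array([b[1] for b in bouts])
    return EventSeries("movement", on, du, np.zeros(on.size))


def test_qc_clean_trace_eligible(mixed_dataset, mixed_analysis):
    qc = mixed_analysis["qc"]
    assert all(res.eligible for res in qc.values())


def test_qc_movement_locked_fails_criterion_2():
    t = np.arange(0, 300, 1 / FS)
    bouts = [(30.0 + 40 * k, 1.5) for k in range(6)]
    sig = np.zeros(t.size)
    for on, _ in bouts:
        sig += 0.8 * _kernel(t - (on + 0.3), 0.2, 1.5)
    rng = np.random.default_rng(0)
    tr = compute_dff(t, 1000 * (1 + sig + rng.normal(0, 0.05, t.size)), (0.0, 20.0))
    res = qc_cell(tr, _movement(bouts))
    assert not res.eligible and not res.criteria[2]


def test_qc_flat_trace_fails_criterion_3():
    t = np.arange(0, 300, 1 / FS)
    rng = np.random.default_rng(1)
    tr = compute_dff(t, 1000 * (1 + rng.normal(0, 0.05, t.size)), (0.0, 20.0))
    res = qc_cell(tr, _movement([]))
    assert not res.eligible and not res.criteria[3]


def test_qc_focal_drift_fails_criterion_4():
    t = np.arange(0, 300, 1 / FS)
    sig = 0.8 * _kernel(t - 50.0, 0.2, 1.5) + 0.8 * _kernel(t - 150.0, 0.2, 1.5)
    drift = 0.10 * t / 60.0
    rng = np.random.default_rng(2)
    tr = compute_dff(t, 1000 * (1 + sig + drift + rng.normal(0, 0.05, t.size)),
                     (0.0, 20.0))
    res = qc_cell(tr, _movement([]))
    assert not res.eligible and not res.criteria[4]


def test_qc_soma_flag_fails_criterion_1():
    t, sig = _events_signal(None, events=[40.0, 80.0])
    tr = compute_dff(t, 1000 * (1 + sig), (0.0, 10.0), meta={"soma_visible": False})
    res = qc_cell(tr, _movement([]))
    assert not res.eligible and not res.criteria[1]


def test_qc_verdicts_gain_invariant():
    t, sig = _events_signal(None, events=[40.0, 80.0])
    rng = np.random.default_rng(4)
    F = 1000 * (1 + sig + rng.normal(0, 0.05, t.size))
    a = qc_cell(compute_dff(t, F, (0.0, 10.0)), _movement([]))
    b = qc_cell(compute_dff(t, 7.0 * F, (0.0, 10.0)), _movement([]))
    assert a.criteria == b.criteria
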