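"""Event-triggered averaging, onset-latency estimation, Ca-ventilation correlation."""

import numpy as np
import pytest

from capnotrace.calcium import CalciumTrace, compute_dff, detect_transients
from capnotrace.events import (
    onset_latency,
    triggered_average,
    ventilation_correlation,
)
from capnotrace.pipeline import analyze_dataset
from capnotrace.plethysmography import EventSeries, compute_ventilation, detect_breaths
from capnotrace.synthetic import SimulationConfig, _kernel, simulate_population

FS = 15.0


def _events(times):
    t = np.asarray(times, dtype=float)
    return EventSeries("exp", t, np.zeros(t.size), np.zeros(t.size))


def _kernel_trace(event_times, duration=200.0, amp=0.8, noise=0.0, seed=0):
    t = np.arange(0, duration, 1 / FS)
    sig = np.zeros(t.size)
    for te in event_times:
        sig += amp * _kernel(t - te, 0.2, 1.5)
    rng = np.random.default_rng(seed)
    return compute_dff(t, 1000 * (1 + sig + rng.normal(0, noise, t.size)), (0.0, 10.0))


def test_triggered_average_zero_trace():
    t = np.arange(0, 100, 1 / FS)
    tr = CalciumTrace("r", t, np.full(t.size, 500.0), 500.0, np.zeros(t.size))
    ta = triggered_average(tr, _events([30.0, 60.0]))
    np.testing.assert_allclose(ta.mean, 0.0)
    assert ta.n_events == 2


def test_triggered_average_peaks_at_zero_lag():
    events = [30.0, 60.0, 90.0, 120.0, 150.0]
    # the kernel peaks ~0.47 s after onset; trigger on the peaks themselves
    peak_delay = 0.2 * 1.5 / 1.3 * np.log(1.5 / 0.2)
    tr = _kernel_trace(events, noise=0.02)
    ta = triggered_average(tr, _events([e + peak_delay for e in events]))
    assert abs(ta.lags_s[int(np.argmax(ta.mean))]) <= 2 / FS


def test_triggered_average_drops_clipped_windows_and_errors():
    tr = _kernel_trace([30.0])
    ta = triggered_average(tr, _events([0.5, 30.0]), window_s=2.0)
    assert ta.n_events == 1 and ta.n_dropped == 1
    with pytest.raises(ValueError):
        triggered_average(tr, _events([0.1]), window_s=2.0)


def test_triggered_average_linearity():
    events = _events([40.0, 80.0, 120.0])
    x = _kernel_trace([40.0, 80.0, 120.0], noise=0.03, seed=1)
    y = _kernel_trace([50.0, 90.0, 130.0], noise=0.03, seed=2)
    combo = CalciumTrace("c", x.times_s, x.F, x.F0, 2.0 * x.dff + 0.5 * y.dff)
    ta_x = triggered_average(x, events)
    ta_y = triggered_average(y, events)
    ta_c = triggered_average(combo, events)
    np.testing.assert_allclose(
        ta_c.mean, 2.0 * ta_x.mean + 0.5 * ta_y.mean, atol=1e-9
    )


def test_shuffled_events_stay_inside_null_band():
    """For events independent of the trace, the average is flat: at most 10%
    of lag points fall outside +/-2 SE of zero."""
    rng = np.random.default_rng(5)
    tr = _kernel_trace(np.sort(rng.uniform(20, 580, 40)), duration=600.0, noise=0.05)
    shuffled = np.sort(rng.uniform(10, 590, 60))
    ta = triggered_average(tr, _events(shuffled))
    se = ta.sd / np.sqrt(ta.n_events)
    frac_outside = np.mean(np.abs(ta.mean) > 2 * se)
    assert frac_outside <= 0.10


def test_latency_zero_when_onsets_coincide():
    events = [30.0, 60.0, 90.0]
    tr = _kernel_trace(events)
    lat = onset_latency(tr, _events(events), ca_onsets=np.array(events))
    np.testing.assert_allclose(lat.leads_s, 0.0)
    assert lat.hist_counts.sum() == 3


@pytest.mark.parametrize("lead", [0.2, 0.5, 1.0])
def test_latency_recovers_configured_lead(lead):
    """Estimator bias stays within 0.1 s across the physiological lead range."""
    cfg = SimulationConfig(
        seed=21, protocol_levels=(0.0, 6.0, 9.0, 0.0), ca_rate=20.0,
        kernel_decay_tau_s=0.7,
    )
    from capnotrace.synthetic import NeuronTemplate

    tpl = NeuronTemplate.for_class(
        "Exp", event_lead_s={0.0: lead, 6.0: lead, 9.0: lead},
        event_lead_jitter_s=0.0,
    )
    ds = simulate_population({"Exp": 2}, cfg, templates={"Exp": tpl})
    out = analyze_dataset(ds.wbp, ds.traces, ds.protocol,
                          movement_channel=ds.movement_channel, seed=21)
    leads = []
    for n in out["neurons"]:
        ons = np.array([e.onset_s for e in n["transients"]])
        lat = onset_latency(n["trace"], out["expirations"], ca_onsets=ons)
        leads.extend(lat.leads_s.tolist())
    assert len(leads) >= 50
    assert abs(np.mean(leads) - lead) <= 0.1


def test_latency_skips_events_without_onsets():
    tr = _kernel_trace([30.0])
    lat = onset_latency(tr, _events([30.0, 150.0]), ca_onsets=np.array([29.9]))
    assert lat.n_skipped == 1
    assert lat.leads_s.size == 1


def test_ventilation_correlation_affine(mixed_dataset):
    ds = mixed_dataset
    vent = compute_ventilation(detect_breaths(ds.wbp))
    t = ds.traces[0].times_s
    vt = np.interp(t, vent.time_s, vent.vt)
    tr = CalciumTrace("r", t, np.ones(t.size), 1.0, 2.0 + 3.0 * vt)
    res = ventilation_correlation(tr, vent, "vt", seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-6)
    assert res.lag_s == 0.0
    assert res.p < 0.01


def test_ventilation_correlation_degenerate_constant(mixed_dataset):
    ds = mixed_dataset
    vent = compute_ventilation(detect_breaths(ds.wbp))
    t = ds.traces[0].times_s
    tr = CalciumTrace("r", t, np.ones(t.size), 1.0, np.full(t.size, 2.0))
    res = ventilation_correlation(tr, vent, "vt", seed=0)
    assert res.degenerate


def test_adapting_neuron_tracks_minute_ventilation():
    """Across the baseline-to-first-step transition, adapting-neuron activity
    correlates positively with V_E (both surge, then partially relax)."""
    rs, ps = [], []
    for seed in (31, 32, 33):
        ds = simulate_population({"E_A": 1}, SimulationConfig(seed=seed))
        vent = compute_ventilation(detect_breaths(ds.wbp))
        tr = ds.traces[0]
        sel = (tr.times_s >= 0.0) & (tr.times_s < 360.0)
        window = CalciumTrace(tr.roi_id, tr.times_s[sel], tr.F[sel], tr.F0,
                              tr.dff[sel])
        res = ventilation_correlation(window, vent, "ve", seed=0)
        rs.append(res.r)
        ps.append(res.p)
    assert all(r > 0 for r in rs)
    assert np.median(ps) < 0.05


def test_independent_noise_gives_weak_correlation():
    rng = np.random.default_rng(7)
    ps, rs = [], []
    ds = simulate_population({"NC": 1}, SimulationConfig(seed=33))
    vent = compute_ventilation(detect_breaths(ds.wbp))
    t = ds.traces[0].times_s
    for k in range(3):
        tr = CalciumTrace("r", t, np.ones(t.size), 1.0,
                          1.0 + rng.normal(0, 0.05, t.size))
        res = ventilation_correlation(tr, vent, "fr", seed=k)
        ps.append(res.p)
        rs.append(abs(res.r))
    assert np.median(ps) > 0.05
    assert np.median(rs) < 0.2
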