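"""Epoch statistics, two-component geometry, and the eight-class rule cascade."""

import numpy as np
import pytest

from capnotrace.calcium import compute_dff
from capnotrace.classification import (
    ClassifierConfig,
    classify_neuron,
    classify_population,
    co2_modulation_test,
    epoch_stats,
    two_component,
)
from capnotrace.plethysmography import EventSeries
from capnotrace.synthetic import SimulationConfig, simulate_population


def _constant_trace(protocol_duration=720.0, rate=15.0):
    t = np.arange(0, protocol_duration, 1 / rate)
    return compute_dff(t, np.full(t.size, 800.0), (0.0, 100.0))


def test_constant_trace_has_zero_deltas(mixed_dataset):
    prot = mixed_dataset.protocol
    st = epoch_stats(_constant_trace(), prot)
    assert st.delta_low == pytest.approx(0.0, abs=1e-12)
    assert st.delta_high == pytest.approx(0.0, abs=1e-12)


def test_two_component_regions():
    def point(dl, dh):
        from capnotrace.classification import EpochStats

        return two_component(
            EpochStats(
                epoch_levels=np.array([0.0, 3.0, 6.0, 0.0]),
                epoch_mean_activity=np.array([0.0, dl, dh, 0.0]),
                epoch_rate=np.zeros(4), epoch_duration_s=np.full(4, 180.0),
                epoch_missing=np.zeros(4, bool),
                baseline_activity=0.0, baseline_rate=0.0,
                delta_low=dl, delta_high=dh, onset_peak=0.0, onset_contrast=0.0,
                late_activity=0.0, adaptation_index=0.0, recovery_activity=0.0,
                recovery_rate=0.0, baseline_smooth_sd=0.0,
            )
        )

    assert point(0.0, 0.0).region == "near-origin"
    assert point(2.0, 1.0).region == "below-identity"     # adapting-consistent
    assert point(1.0, 2.0).region == "above-identity"     # graded-consistent
    assert point(-1.0, -1.0).region == "negative-quadrant"


def test_generator_deltas_match_class_geometry(mixed_analysis, true_labels):
    for r in mixed_analysis["classifications"]:
        lbl = true_labels[r.roi_id]
        if lbl == "E_G":
            assert r.stats.delta_high > r.stats.delta_low > 0
        if lbl == "I":
            assert r.stats.delta_low < 0 and r.stats.delta_high < 0


def test_quadrant_placement_of_generator_classes(mixed_analysis, true_labels):
    """>= 90% of adapting/graded/inhibited/non-coding neurons land in the
    two-component region their class predicts."""
    predicted = {
        "E_A": "below-identity",
        "E_G": "above-identity",
        "I": "negative-quadrant",
        "NC": "near-origin",
    }
    hits = total = 0
    for r in mixed_analysis["classifications"]:
        lbl = true_labels[r.roi_id]
        if lbl in predicted:
            total += 1
            hits += r.point.region == predicted[lbl]
    assert total >= 12
    assert hits / total >= 0.9


def test_label_recovery_and_composition_accounting(mixed_analysis, true_labels):
    results = mixed_analysis["classifications"]
    assert all(r.label in
               {"I", "E_A", "E_G", "T", "Sn", "Exp", "NC", "NC-RR", "unclassifiable"}
               for r in results)
    summary = mixed_analysis["summary"]
    assert sum(summary["counts"].values()) == summary["n_classified"]
    acc = np.mean([r.label == true_labels[r.roi_id] for r in results])
    assert acc >= 0.9
    # the decision trail records every rule evaluated up to the winner
    for r in results:
        assert r.decision_trail[-1][1] is True or r.label == "unclassifiable"


def test_classification_gain_invariant(mixed_dataset, mixed_analysis):
    """Scaling raw fluorescence leaves every label unchanged (dff is scale-free)."""
    from capnotrace.pipeline import analyze_dataset

    ds = mixed_dataset
    scaled = []
    for tr in ds.traces[:8]:
        scaled.append(
            compute_dff(tr.times_s, 5.0 * tr.F,
                        (0.0, ds.config.epoch_durations[0]),
                        roi_id=tr.roi_id, meta=tr.meta)
        )
    out = analyze_dataset(ds.wbp, scaled, ds.protocol,
                          movement_channel=ds.movement_channel, seed=1)
    original = {r.roi_id: r.label for r in mixed_analysis["classifications"]}
    for r in out["classifications"]:
        assert r.label == original[r.roi_id]


def test_classification_invariant_under_resampling(mixed_dataset, mixed_analysis):
    """Decimating 15 -> 7.5 frames/s (half the rate) preserves labels."""
    from capnotrace.pipeline import analyze_dataset

    ds = mixed_dataset
    halved = [
        compute_dff(tr.times_s[::2], tr.F[::2],
                    (0.0, ds.config.epoch_durations[0]),
                    roi_id=tr.roi_id, meta=tr.meta)
        for tr in ds.traces[:8]
    ]
    out = analyze_dataset(ds.wbp, halved, ds.protocol,
                          movement_channel=ds.movement_channel, seed=1)
    original = {r.roi_id: r.label for r in mixed_analysis["classifications"]}
    agree = [r.label == original[r.roi_id] for r in out["classifications"]]
    assert np.mean(agree) >= 0.85


def test_missing_epoch_marks_unclassifiable(mixed_dataset):
    ds = mixed_dataset
    trace = ds.traces[0]
    base = ds.protocol.effective_epochs()[1]
    movement = EventSeries(
        "movement", np.array([base.start_s]), np.array([base.duration_s]),
        np.zeros(1),
    )
    st = epoch_stats(trace, ds.protocol, movement=movement)
    assert st.has_missing_epoch
    res = classify_neuron(st, config=ClassifierConfig())
    assert res.label == "unclassifiable"


def test_empty_population():
    results, table, summary = classify_population([])
    assert results == [] and len(table) == 0
    assert summary["n_total"] == 0
    assert all(v == 0 for v in summary["counts"].values())


def test_modulation_test_flags_graded_not_constant(mixed_dataset):
    prot = mixed_dataset.protocol
    graded = next(
        tr for tr, n in zip(mixed_dataset.traces, mixed_dataset.truth.neurons)
        if n.class_label == "E_G"
    )
    assert co2_modulation_test(graded, prot) < 0.01
    assert co2_modulation_test(_constant_trace(), prot) == 1.0
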