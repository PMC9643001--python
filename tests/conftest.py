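import numpy as np
import pytest

from capnotrace.pipeline import analyze_dataset
from capnotrace.synthetic import SimulationConfig, simulate_breathing, simulate_population

BENCH_COMPOSITION = {"E_A": 4, "E_G": 3, "I": 3, "T": 3, "Sn": 2, "NC": 5, "NC-RR": 4}


@pytest.fixture(scope="session")
def breathing_session():
    """One simulated WBP session with known behavioral ground truth."""
    config = SimulationConfig(seed=1)
    wbp, movement, truth = simulate_breathing(config)
    return config, wbp, movement, truth


@pytest.fixture(scope="session")
def mixed_dataset():
    """A 24-neuron population covering all generator classes (seed 1)."""
    return simulate_population(BENCH_COMPOSITION, SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def mixed_analysis(mixed_dataset):
    """Full pipeline output for the mixed population."""
    ds = mixed_dataset
    return analyze_dataset(
        ds.wbp, ds.traces, ds.protocol,
        movement_channel=ds.movement_channel, seed=1,
    )


@pytest.fixture(scope="session")
def true_labels(mixed_dataset):
    return {n.roi_id: n.class_label for n in mixed_dataset.truth.neurons}


@pytest.fixture(scope="session")
def event_recall():
    """Scorer: fraction of true events explained by a detection.

    A true event counts as recovered when a detected onset lies within
    ``tol_s`` of it, or when it falls inside the ``cover_s`` span after a
    detection (two true events closer than the indicator decay merge into a
    single detection that covers both).
    """

    def _recall(detected_onsets, true_events, tol_s=0.5, cover_s=3.0):
        det = np.asarray(detected_onsets)
        hit = 0
        for t in true_events:
            if det.size and np.min(np.abs(det - t)) <= tol_s:
                hit += 1
            elif det.size and np.any((det <= t) & (t <= det + cover_s)):
                hit += 1
        return hit / max(len(true_events), 1)

    return _recall
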