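"""Canonical study configurations and end-to-end recovery experiments.

These bundle the three recording preparations the pipeline targets — RTN and
Raphe sessions on the 0-3-6-0% CO2 protocol with the slow indicator, and
lateral-parafacial (pF_L) sessions on the 0-6-9-0% protocol with the fast
indicator — together with the reported class compositions, so that label-
and parameter-recovery experiments can be run with one call.
"""

from __future__ import annotations

import numpy as np

from ._utils import child_seed
from .events import onset_latency
from .pipeline import analyze_dataset
from .synthetic import SimulationConfig, simulate_population

#: class composition of the retrotrapezoid-nucleus dataset (98 neurons)
RTN_COMPOSITION = {"E_A": 27, "E_G": 4, "I": 5, "Sn": 3, "T": 5, "NC": 35, "NC-RR": 19}
#: class composition of the medullary-raphe dataset (26 neurons)
RAPHE_COMPOSITION = {"E_G": 8, "E_A": 4, "I": 10, "NC": 4}
#: number of active expiratory neurons recorded in the pF_L
PFL_N_NEURONS = 20
#: configured Ca-onset leads before active expiration, per CO2 level (s)
PFL_LEADS = {6.0: 0.5, 9.0: 0.3}
#: range of Ca-onset leads before sniff bouts (s)
SNIFF_LEAD_RANGE = (0.4, 0.8)
#: QC accounting: candidate ROI traces recorded, and defective ones among them
QC_TOTAL_CANDIDATES = 194
QC_DEFECT_COUNTS = {"movement_locked": 20, "flat": 15, "focal_drift": 15}
#: a mixed composition scaled to the full candidate count, defects injected on top
QC_COMPOSITION = {"E_A": 54, "E_G": 8, "I": 10, "Sn": 6, "T": 10, "NC": 70, "NC-RR": 36}


def _run(composition, config, seed, defects=None, templates=None):
    dataset = simulate_population(composition, config, defects=defects,
                                  templates=templates)
    out = analyze_dataset(
        dataset.wbp, dataset.traces, dataset.protocol,
        movement_channel=dataset.movement_channel, seed=seed,
    )
    out["dataset"] = dataset
    out["truth_labels"] = {n.roi_id: n.class_label for n in dataset.truth.neurons}
    return out


def run_rtn_recovery(seed: int) -> dict:
    """Simulate the 98-neuron RTN session and classify it."""
    return _run(RTN_COMPOSITION, SimulationConfig(seed=child_seed(seed, 10)), seed)


def run_raphe_recovery(seed: int) -> dict:
    """Simulate the 26-neuron Raphe session and classify it."""
    return _run(RAPHE_COMPOSITION, SimulationConfig(seed=child_seed(seed, 11)), seed)


def run_pfl_recovery(seed: int) -> dict:
    """Simulate the pF_L expiratory population and recover onset latencies.

    Uses the fast indicator (shorter decay) at 20 frames/s on the 0-6-9-0%
    protocol.  Returns the classification output plus per-level pooled lead
    summaries and the per-neuron median leads.
    """
    config = SimulationConfig(
        seed=child_seed(seed, 12),
        protocol_levels=(0.0, 6.0, 9.0, 0.0),
        ca_rate=20.0,
        kernel_decay_tau_s=0.7,
    )
    out = _run({"Exp": PFL_N_NEURONS}, config, seed)
    leads_by_level: dict = {lvl: [] for lvl in PFL_LEADS}
    median_leads = []
    for n in out["neurons"]:
        onsets = np.array([ev.onset_s for ev in n["transients"]])
        lat = onset_latency(
            n["trace"], out["expirations"], ca_onsets=onsets,
            protocol=out["dataset"].protocol,
        )
        median_leads.append(lat.median_lead_s)
        for e, lead in zip(lat.event_times_s, lat.leads_s):
            lvl = out["dataset"].protocol.level_at(e)
            if lvl in leads_by_level:
                leads_by_level[lvl].append(lead)
    out["leads_by_level"] = {k: np.array(v) for k, v in leads_by_level.items()}
    out["median_leads"] = np.array(median_leads)
    return out


def run_sniff_recovery(seed: int, n_neurons: int = 4) -> dict:
    """Simulate sniff-coding neurons and recover their leads over the bouts.

    The bout rate is raised so a single session provides at least 50 sniff
    bouts to average over.
    """
    config = SimulationConfig(seed=child_seed(seed, 13), sniff_rate_per_min=6.0)
    out = _run({"Sn": n_neurons}, config, seed)
    leads = []
    per_neuron_means = []
    for n in out["neurons"]:
        onsets = np.array([ev.onset_s for ev in n["transients"]])
        lat = onset_latency(n["trace"], out["sniffs"], ca_onsets=onsets)
        leads.extend(lat.leads_s.tolist())
        per_neuron_means.append(lat.mean_lead_s)
    out["sniff_leads"] = np.array(leads)
    out["sniff_lead_means_per_neuron"] = np.array(per_neuron_means)
    return out


def run_qc_accounting(seed: int) -> dict:
    """Simulate the full candidate pool with injected defects and run QC."""
    out = _run(
        QC_COMPOSITION,
        SimulationConfig(seed=child_seed(seed, 14)),
        seed,
        defects=QC_DEFECT_COUNTS,
    )
    out["n_eligible"] = sum(res.eligible for res in out["qc"].values())
    return out
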