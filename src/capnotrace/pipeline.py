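"""End-to-end orchestration: simulate or load, analyze, classify, report.

A single master seed fans out to per-stage and per-neuron seeds through
``numpy.random.SeedSequence``, so a full run is reproducible bit-for-bit:
identical config + seed gives an identical report.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from ._utils import child_seed
from .calcium import detect_transients, qc_cell
from .classification import (
    ClassifierConfig,
    EventEvidence,
    classify_population,
    co2_modulation_test,
    epoch_stats,
    plot_two_component,
)
from .events import event_regressor_test, onset_latency
from .io import read_dataset, write_dataset
from .plethysmography import (
    EventSeries,
    compute_ventilation,
    detect_active_expiration,
    detect_breaths,
    detect_sniff_bouts,
    movement_sonogram,
)
from .synthetic import SimulationConfig, simulate_population


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: Optional[str] = None
    # either simulate ...
    composition: Optional[dict] = None
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    defects: Optional[dict] = None
    # ... or load
    input_dir: Optional[str] = None
    # thresholds
    transient_z: float = 3.0
    sniff_min_duration_s: float = 0.5
    exp_trough_z: float = 4.0
    movement_z: float = 4.0
    latency_window_s: float = 2.0
    classifier: dict = field(default_factory=dict)   # ClassifierConfig overrides

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.composition is None and cfg.input_dir is None:
            raise ValueError("config must give either a composition or an input_dir")
        sim_names = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(cfg.simulation) - sim_names
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        cls_names = {f.name for f in dataclasses.fields(ClassifierConfig)}
        unknown = set(cfg.classifier) - cls_names
        if unknown:
            raise ValueError(f"unknown classifier keys: {sorted(unknown)}")
        return cfg


@dataclass
class RunReport:
    """Run accounting mirroring the study's inclusion/exclusion flow."""

    version: str
    seed: int
    n_candidates: int
    n_eligible: int
    qc_failures_by_criterion: dict
    composition: dict
    latency_by_level: dict
    manifest: list
    config_echo: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _drop_in_movement(
    events: EventSeries, movement: EventSeries, margin_s: float = 0.25
) -> EventSeries:
    """Remove behavioral events whose onset falls inside a movement bout."""
    if len(events) == 0 or len(movement) == 0:
        return events
    padded = EventSeries(
        movement.kind,
        movement.onsets_s - margin_s,
        movement.durations_s + 2 * margin_s,
        movement.magnitudes,
    )
    keep = ~padded.contains(events.onsets_s)
    return EventSeries(
        events.kind,
        events.onsets_s[keep],
        events.durations_s[keep],
        events.magnitudes[keep],
        meta=dict(events.meta),
    )


def _fr_residual(vent, protocol) -> np.ndarray:
    """Respiratory-frequency variability after removing the CO2 response.

    Each delay-corrected epoch's f_R is modelled as a step plus an
    exponentially adapting onset transient (a + b exp(-t/tau)); the residual
    isolates the within-epoch variability of breathing frequency that the
    respiratory-related (NC-RR) class codes.  A linear model avoids the
    phase distortion a running-median detrend imposes on slow rhythms.

    The residual is winsorized at 3 robust SD (sniff and artefact spikes)
    and zeroed for the first 60 s after every epoch boundary: during the
    transitions the CO2-driven change in f_R cannot be separated from
    spontaneous variability, so those windows carry no evidence either way.
    """
    from scipy.optimize import curve_fit

    from ._utils import mad_sd

    t = vent.time_s
    y = vent.fr.astype(float)
    resid = np.zeros_like(y)
    eff = protocol.effective_epochs()
    starts = np.array([ep.start_s for ep in eff])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(eff) - 1)
    for i in range(len(eff)):
        m = idx == i
        if not np.any(m):
            continue
        ts = t[m] - t[m][0]
        ys = y[m].copy()
        s = mad_sd(ys)
        if s > 0:   # keep sniff/artefact spikes out of the trend fit
            med = float(np.median(ys))
            ys_fit = np.clip(ys, med - 3 * s, med + 3 * s)
        else:
            ys_fit = ys
        model = lambda u, a, b, tau: a + b * np.exp(-u / tau)  # noqa: E731
        try:
            p0 = [float(np.median(ys_fit)),
                  float(ys_fit[: max(3, ys_fit.size // 10)].mean() - np.median(ys_fit)),
                  45.0]
            popt, _ = curve_fit(
                model, ts, ys_fit, p0=p0,
                bounds=([0.0, -600.0, 5.0], [2000.0, 600.0, 300.0]), maxfev=2000,
            )
            resid[m] = y[m] - model(ts, *popt)
        except (RuntimeError, ValueError):
            resid[m] = y[m] - float(np.median(ys_fit))
    s = mad_sd(resid)
    if s > 0:
        med = float(np.median(resid))
        np.clip(resid, med - 3 * s, med + 3 * s, out=resid)
    for ep in eff:
        resid[(t >= ep.start_s) & (t < ep.start_s + 60.0)] = 0.0
    return resid


def analyze_dataset(
    wbp,
    traces,
    protocol,
    movement_channel=None,
    seed: int = 0,
    transient_z: float = 3.0,
    sniff_min_duration_s: float = 0.5,
    exp_trough_z: float = 4.0,
    movement_z: float = 4.0,
    latency_window_s: float = 2.0,
    classifier: Optional[ClassifierConfig] = None,
    run_qc: bool = True,
):
    """Run the full analysis on an in-memory dataset.

    Returns a dict with the breath table, ventilation series, detected
    behavioral events, per-ROI QC results, classifications, the population
    table and the composition summary.
    """
    breaths = detect_breaths(wbp)
    vent = compute_ventilation(breaths)
    sniffs = detect_sniff_bouts(vent, min_duration_s=sniff_min_duration_s)
    exps = detect_active_expiration(wbp, breaths, exp_trough_z, protocol=protocol)
    channel = movement_channel if movement_channel is not None else wbp.samples
    _, _, _, movement = movement_sonogram(channel, wbp.rate, z_threshold=movement_z)
    # movement artefacts mimic sniff-like pseudo-breaths and deep troughs on
    # the WBP channel; behavioral events inside movement bouts are artefactual
    sniffs = _drop_in_movement(sniffs, movement)
    exps = _drop_in_movement(exps, movement)

    fr_resid = _fr_residual(vent, protocol)

    qc_results = {}
    eligible = []
    for trace in traces:
        res = qc_cell(trace, movement, z_threshold=transient_z)
        qc_results[trace.roi_id] = res
        if res.eligible or not run_qc:
            eligible.append(trace)

    neurons = []
    for trace in eligible:
        transients = detect_transients(trace, z_threshold=transient_z)
        onsets = np.array([ev.onset_s for ev in transients])
        stats = epoch_stats(trace, protocol, movement=movement, transients=transients)
        roi_key = zlib.crc32(trace.roi_id.encode()) % 2**16
        stats.mod_p = co2_modulation_test(
            trace, protocol, seed=child_seed(seed, 2, roi_key)
        )
        sniff_ev = EventEvidence.from_latency(
            onset_latency(trace, sniffs, window_s=latency_window_s, ca_onsets=onsets)
        ) if len(sniffs) else None
        exp_ev = EventEvidence.from_latency(
            onset_latency(trace, exps, window_s=latency_window_s, ca_onsets=onsets)
        ) if len(exps) else None
        # respiratory-relatedness: are this neuron's events concentrated at
        # moments of high fR variability (CO2 response removed)?
        fr_corr = event_regressor_test(
            onsets, vent.time_s, fr_resid, lags_s=np.array([0.25]),
            seed=child_seed(seed, 3, roi_key),
        )
        neurons.append(
            {
                "roi_id": trace.roi_id,
                "trace": trace,
                "stats": stats,
                "transients": transients,
                "sniff_evidence": sniff_ev,
                "exp_evidence": exp_ev,
                "fr_correlation": fr_corr,
            }
        )
    results, table, summary = classify_population(neurons, classifier)

    latency_by_level: dict = {}
    if len(exps):
        for n, r in zip(neurons, results):
            if r.label != "Exp":
                continue
            onsets = np.array([ev.onset_s for ev in n["transients"]])
            lat = onset_latency(
                n["trace"], exps, window_s=latency_window_s,
                protocol=protocol, ca_onsets=onsets,
            )
            for lvl, summ in lat.by_level.items():
                bucket = latency_by_level.setdefault(
                    lvl, {"n": 0, "leads": []}
                )
                bucket["n"] += summ["n"]
                bucket["leads"].append(summ["mean_lead_s"])
    for lvl, bucket in latency_by_level.items():
        leads = bucket.pop("leads")
        bucket["mean_lead_s"] = round(float(np.mean(leads)), 4)

    return {
        "breaths": breaths,
        "ventilation": vent,
        "sniffs": sniffs,
        "expirations": exps,
        "movement": movement,
        "qc": qc_results,
        "neurons": neurons,
        "classifications": results,
        "table": table,
        "summary": summary,
        "latency_by_level": latency_by_level,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write every output named in the manifest."""
    outdir = Path(config.outdir) if config.outdir else None
    manifest: list[str] = []

    if config.input_dir is not None:
        stage = "read_dataset"
        try:
            wbp, traces, protocol, extras = read_dataset(config.input_dir)
            movement_channel = extras.get("movement_channel")
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    else:
        stage = "simulate"
        try:
            sim = SimulationConfig(seed=config.seed, **config.simulation)
            dataset = simulate_population(
                config.composition, sim, defects=config.defects
            )
            wbp, traces, protocol = dataset.wbp, dataset.traces, dataset.protocol
            movement_channel = dataset.movement_channel
            if outdir is not None:
                manifest += write_dataset(dataset, outdir / "dataset")
        except ValueError as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    classifier = ClassifierConfig(**config.classifier)
    out = analyze_dataset(
        wbp,
        traces,
        protocol,
        movement_channel=movement_channel,
        seed=config.seed,
        transient_z=config.transient_z,
        sniff_min_duration_s=config.sniff_min_duration_s,
        exp_trough_z=config.exp_trough_z,
        movement_z=config.movement_z,
        latency_window_s=config.latency_window_s,
        classifier=classifier,
    )

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

        def save(name, writer):
            path = outdir / name
            writer(path)
            manifest.append(str(path))

        save("breaths.csv", lambda p: out["breaths"].to_frame().to_csv(p, index=False))
        save("ventilation.csv",
             lambda p: out["ventilation"].to_frame().to_csv(p, index=False))
        from .io import write_events_csv

        save("behavioral_events.csv",
             lambda p: write_events_csv(
                 p, [out["sniffs"], out["expirations"], out["movement"]]))
        import pandas as pd

        qc_rows = [
            {"roi_id": rid, "eligible": res.eligible,
             **{f"criterion_{k}": v for k, v in res.criteria.items()},
             "reasons": "; ".join(res.reasons)}
            for rid, res in out["qc"].items()
        ]
        save("qc.csv", lambda p: pd.DataFrame(qc_rows).to_csv(p, index=False))
        save("classification.csv", lambda p: out["table"].to_csv(p, index=False))
        save("composition.json",
             lambda p: Path(p).write_text(json.dumps(out["summary"], indent=1,
                                                     sort_keys=True)))
        if out["classifications"]:
            save("two_component.png",
                 lambda p: plot_two_component(out["classifications"], path=p))

    qc_fail = {
        k: sum(1 for res in out["qc"].values() if not res.criteria[k])
        for k in (1, 2, 3, 4)
    }
    report = RunReport(
        version=__version__,
        seed=config.seed,
        n_candidates=len(traces),
        n_eligible=sum(res.eligible for res in out["qc"].values()),
        qc_failures_by_criterion=qc_fail,
        composition=out["summary"],
        latency_by_level=out["latency_by_level"],
        manifest=sorted(manifest),
        config_echo=dataclasses.asdict(config),
    )
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json())
    return report
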