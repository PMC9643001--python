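"""CSV/YAML/JSON dialects for datasets, and their validated readers.

All times are seconds from recording start (0-based, half-open intervals).
Fixed headers:

* WBP / movement CSV: ``time_s,pressure``
* Ca CSV: ``time_s`` plus one column per ROI
* events CSV: ``time_s,type,duration_s,magnitude``
* config YAML: the simulation / protocol parameters
* truth JSON: per-neuron labels, parameters and event times
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .calcium import CalciumTrace, compute_dff
from .plethysmography import EventSeries, PlethysmographyTrace
from .protocol import GasProtocol
from .synthetic import SimulationConfig, SyntheticDataset


class SchemaError(ValueError):
    """A file violated the documented dialect."""


def _require_monotonic(time: np.ndarray, path) -> None:
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        # +3: one for the header line, one for 0-based indexing, one because
        # the violation is the second element of the offending pair
        raise SchemaError(
            f"{path}: time_s not strictly increasing at data row {int(bad[0]) + 3}"
        )


def write_wbp_csv(path, trace: PlethysmographyTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "pressure": trace.samples}).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_wbp_csv(
    path, body_mass_g: float = 25.0, calibration_ml_per_unit: float = 1.0
) -> PlethysmographyTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "pressure"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    _require_monotonic(t, path)
    rate = 1.0 / float(np.median(np.diff(t)))
    return PlethysmographyTrace(
        df["pressure"].to_numpy(float), rate, body_mass_g, calibration_ml_per_unit
    )


def write_calcium_csv(path, traces: list[CalciumTrace], raw: bool = True) -> None:
    if not traces:
        raise ValueError("no traces to write")
    data = {"time_s": traces[0].times_s}
    for tr in traces:
        data[tr.roi_id] = tr.F if raw else tr.dff
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.7g")


def read_calcium_csv(
    path, baseline_window: tuple[float, float]
) -> list[CalciumTrace]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing column 'time_s'")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: no ROI columns")
    t = df["time_s"].to_numpy(float)
    _require_monotonic(t, path)
    return [
        compute_dff(t, df[c].to_numpy(float), baseline_window, roi_id=str(c))
        for c in df.columns
        if c != "time_s"
    ]


def write_events_csv(path, events: list[EventSeries]) -> None:
    frames = [ev.to_frame() for ev in events if len(ev)]
    df = (
        pd.concat(frames).sort_values("time_s", kind="stable")
        if frames
        else pd.DataFrame(columns=["time_s", "type", "duration_s", "magnitude"])
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_events_csv(path) -> dict[str, EventSeries]:
    df = pd.read_csv(path)
    for col in ("time_s", "type", "duration_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out = {}
    for kind, grp in df.groupby("type"):
        grp = grp.sort_values("time_s")
        out[str(kind)] = EventSeries(
            str(kind),
            grp["time_s"].to_numpy(float),
            grp["duration_s"].to_numpy(float),
            grp["magnitude"].to_numpy(float)
            if "magnitude" in grp
            else np.zeros(len(grp)),
        )
    return out


def write_config_yaml(path, config: SimulationConfig) -> None:
    d = dataclasses.asdict(config)
    for key in ("protocol_levels", "epoch_durations", "sniff_duration_s",
                "movement_duration_s"):
        d[key] = list(d[key])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - names
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("protocol_levels", "epoch_durations", "sniff_duration_s",
                "movement_duration_s"):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("fr_multipliers", "vt_multipliers", "exp_rates_per_s"):
        if key in d:
            d[key] = {float(k): float(v) for k, v in d[key].items()}
    return SimulationConfig(**d)


def write_truth_json(path, dataset: SyntheticDataset) -> None:
    truth = dataset.truth
    payload = {
        "epoch_levels": truth.epoch_levels.tolist(),
        "epoch_starts_s": truth.epoch_starts_s.tolist(),
        "sniff_onsets_s": truth.sniff_onsets_s.tolist(),
        "exp_onsets_s": truth.exp_onsets_s.tolist(),
        "movement_onsets_s": truth.movement_onsets_s.tolist(),
        "movement_durations_s": truth.movement_durations_s.tolist(),
        "neurons": [
            {
                "roi_id": n.roi_id,
                "class_label": n.class_label,
                "defect": n.defect,
                "params": n.params,
                "event_times_s": np.round(n.event_times_s, 4).tolist(),
            }
            for n in truth.neurons
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_dataset(dataset: SyntheticDataset, outdir) -> list[str]:
    """Write a synthetic dataset in the documented dialects; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def out(name):
        paths.append(str(outdir / name))
        return outdir / name

    write_wbp_csv(out("wbp.csv"), dataset.wbp)
    pd.DataFrame(
        {"time_s": dataset.wbp.times, "pressure": dataset.movement_channel}
    ).to_csv(out("movement.csv"), index=False, float_format="%.6g")
    write_calcium_csv(out("calcium.csv"), dataset.traces)
    truth = dataset.truth
    write_events_csv(
        out("events.csv"),
        [
            EventSeries("sniff", truth.sniff_onsets_s, truth.sniff_durations_s,
                        np.zeros(truth.sniff_onsets_s.size)),
            EventSeries("expiration", truth.exp_onsets_s,
                        np.zeros(truth.exp_onsets_s.size),
                        np.zeros(truth.exp_onsets_s.size)),
            EventSeries("movement", truth.movement_onsets_s,
                        truth.movement_durations_s,
                        np.zeros(truth.movement_onsets_s.size)),
        ],
    )
    write_config_yaml(out("config.yaml"), dataset.config)
    write_truth_json(out("truth.json"), dataset)
    return paths


def read_dataset(
    directory,
    body_mass_g: Optional[float] = None,
) -> tuple[PlethysmographyTrace, list[CalciumTrace], GasProtocol, dict]:
    """Read a dataset directory back into validated in-memory objects.

    Returns ``(wbp, traces, protocol, extras)`` where ``extras`` carries the
    movement channel, any events file content and the raw config.
    """
    directory = Path(directory)
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing config file: {cfg_path}")
    config = read_config_yaml(cfg_path)
    if body_mass_g is not None:
        config = dataclasses.replace(config, body_mass_g=body_mass_g)
    wbp_path = directory / "wbp.csv"
    if not wbp_path.exists():
        raise FileNotFoundError(f"missing WBP file: {wbp_path}")
    wbp = read_wbp_csv(wbp_path, config.body_mass_g, config.calibration_ml_per_unit)
    ca_path = directory / "calcium.csv"
    if not ca_path.exists():
        raise FileNotFoundError(f"missing calcium file: {ca_path}")
    baseline_end = float(config.epoch_durations[0])
    traces = read_calcium_csv(ca_path, (0.0, baseline_end))
    protocol = config.protocol()
    extras: dict = {"config": config}
    mv_path = directory / "movement.csv"
    if mv_path.exists():
        extras["movement_channel"] = pd.read_csv(mv_path)["pressure"].to_numpy(float)
    ev_path = directory / "events.csv"
    if ev_path.exists():
        extras["events"] = read_events_csv(ev_path)
    return wbp, traces, protocol, extras
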