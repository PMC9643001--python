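"""Eight-class response classification of chemosensory neurons.

Each QC-passing neuron is assigned exactly one of:

* ``Exp`` — expiratory: transients time-locked to, and preceding, active
  expiration events;
* ``Sn`` — sniff-coding: transients time-locked to, and preceding, sniff
  bouts;
* ``I`` — inhibited: spontaneously active at rest, activity greatly reduced
  at both hypercapnic levels;
* ``E_A`` — excited-adapting: a burst at the first CO2 step that decays,
  marking the beginning (and, via rebound, the end) of hypercapnia;
* ``E_G`` — excited-graded: activity grows with the CO2 level and returns to
  baseline on washout;
* ``T`` — tonic: active throughout, unmodulated by CO2;
* ``NC-RR`` — non-coding respiratory-related: no CO2 coding but correlated
  with variability in breathing frequency;
* ``NC`` — non-coding: everything else.

The rules are evaluated in that priority order: behavioral-event classes
outrank CO2 classes because their evidence is time-locked and specific, and
the cascade guarantees a single label.  The two-component analysis — the
change in Ca activity at the higher CO2 level versus the change at the lower
level, relative to the identity line — separates adapting (below identity)
from graded (above identity) responders and places inhibited neurons in the
negative quadrant and non-coders near the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._utils import mad_sd
from .calcium import CalciumTrace, TransientEvent
from .events import CorrelationResult, LatencyEstimate
from .plethysmography import EventSeries
from .protocol import GasProtocol

CLASS_LABELS = ("I", "E_A", "E_G", "T", "Sn", "Exp", "NC", "NC-RR")
CO2_MODULATED = ("I", "E_A", "E_G")


@dataclass
class EpochStats:
    """Protocol-aligned activity statistics for one neuron.

    Activity is dff minus its baseline-epoch median, so a silent neuron sits
    at 0.  ``delta_low``/``delta_high`` are the changes from baseline at the
    two hypercapnic levels (the two-component coordinates).
    """

    epoch_levels: np.ndarray         # CO2 % per epoch, protocol order
    epoch_mean_activity: np.ndarray  # mean activity per (delay-corrected) epoch
    epoch_rate: np.ndarray           # transient onsets / s per epoch
    epoch_duration_s: np.ndarray     # effective epoch duration inside the record
    epoch_missing: np.ndarray        # epochs fully inside movement bouts
    baseline_activity: float
    baseline_rate: float
    delta_low: float                 # A(first hypercapnic level) - A(baseline)
    delta_high: float                # A(second hypercapnic level) - A(baseline)
    onset_peak: float                # peak smoothed activity, first W s of CO2
    onset_contrast: float            # onset-window mean minus rest-of-CO2 mean
    late_activity: float             # mean activity, end of hypercapnia
    adaptation_index: float          # 1 - late / onset_peak (when peak > 0)
    recovery_activity: float
    recovery_rate: float
    baseline_smooth_sd: float        # robust SD of smoothed baseline activity
    mod_p: float = np.nan            # block-permutation p for CO2 modulation

    @property
    def has_missing_epoch(self) -> bool:
        return bool(np.any(self.epoch_missing))


@dataclass
class EventEvidence:
    """Summary of event-locked latency evidence for the Sn/Exp rules."""

    n_matched: int
    median_lead_s: float
    lead_iqr_s: float
    pos_fraction: float
    p_sign: float

    @classmethod
    def from_latency(cls, lat: LatencyEstimate) -> "EventEvidence":
        leads = lat.leads_s
        if leads.size == 0:
            return cls(0, np.nan, np.nan, np.nan, 1.0)
        q75, q25 = np.percentile(leads, [75, 25])
        return cls(
            n_matched=int(leads.size),
            median_lead_s=float(np.median(leads)),
            lead_iqr_s=float(q75 - q25),
            pos_fraction=float(np.mean(leads > 0)),
            p_sign=float(lat.p_sign),
        )


@dataclass
class TwoComponentPoint:
    delta_low: float
    delta_high: float
    region: str                  # above-identity | below-identity | near-origin | negative-quadrant
    on_band: bool                # within the identity band of half-width delta


@dataclass
class NeuronClassification:
    roi_id: str
    label: str
    stats: EpochStats
    point: TwoComponentPoint
    sniff_evidence: Optional[EventEvidence]
    exp_evidence: Optional[EventEvidence]
    fr_correlation: Optional[CorrelationResult]
    decision_trail: list = field(default_factory=list)


@dataclass
class ClassifierConfig:
    """Every threshold of the rule cascade, with documented defaults."""

    # behavioral-event rules (Sn, Exp)
    event_min_matched: int = 8
    event_alpha: float = 0.002
    event_min_median_lead_s: float = 0.1
    event_max_median_lead_s: float = 1.5
    event_max_iqr_s: float = 0.6
    event_min_pos_fraction: float = 0.7
    # inhibited
    inhibited_fraction: float = 0.2       # drop below median >= this x baseline activity
    inhibited_rate_fraction: float = 0.75  # corroborating drop in event rate
    inhibited_min_drop: float = 0.04      # dF/F0 below baseline median, both epochs
    inhibited_deep_drop: float = 0.06     # at this depth no corroboration is needed
    min_baseline_rate: float = 0.05       # events/s for "active at rest"
    min_baseline_activity: float = 0.02   # dF/F0 floor for a meaningful ratio
    # excited-adapting
    adaptation_cutoff: float = 0.5
    onset_window_s: float = 60.0
    onset_z: float = 3.0
    onset_min_peak: float = 0.25          # dF/F0: floor for a real burst
    onset_min_contrast: float = 0.25      # dF/F0: burst vs rest of hypercapnia
    ea_max_baseline_activity: float = 0.12  # "silent or low level activity at rest"
    # tonic
    tonic_min_rate: float = 0.09          # events/s over the whole record
    tonic_uniformity: float = 0.4         # min epoch rate as fraction of overall
    t_mod_alpha: float = 0.01             # CO2 veto for tonic (strict: T is the default
                                          # for uniform firing, so weak evidence must not
                                          # strip it)
    # CO2-modulation permutation test
    mod_alpha: float = 0.05
    n_permutations: int = 999
    block_s: float = 20.0
    perm_seed: int = 0
    # excited-graded
    eg_min_delta: float = 0.5             # dF/F0: floor for a graded response
    eg_mod_alpha: float = 0.05            # with the delta floor, standard alpha suffices
    # NC-RR
    fr_alpha: float = 0.05                # for claiming respiratory-relatedness
    nc_rr_max_delta: float = 0.5          # dF/F0: above this it is CO2 coding
    # two-component geometry (absolute floors; classify_population scales
    # them up to 0.5x / 0.25x the population robust SD of the deltas, capped
    # so a responder-dominated population cannot swallow genuine responses
    # into the near-origin region)
    near_origin_radius: float = 0.12
    identity_band: float = 0.04
    near_origin_radius_max: float = 0.16
    identity_band_max: float = 0.075
    # recovery ("returned to baseline upon removal of the stimulus")
    recovery_fraction: float = 0.5


# ---------------------------------------------------------------------------


def _epoch_frame_masks(
    times: np.ndarray, protocol: GasProtocol
) -> list[np.ndarray]:
    masks = []
    for ep in protocol.effective_epochs():
        masks.append((times >= ep.start_s) & (times < ep.end_s))
    return masks


def epoch_stats(
    trace: CalciumTrace,
    protocol: GasProtocol,
    movement: Optional[EventSeries] = None,
    transients: Optional[Sequence[TransientEvent]] = None,
    smooth_s: float = 10.0,
    onset_window_s: float = 60.0,
    late_window_s: float = 60.0,
) -> EpochStats:
    """Per-epoch activity statistics on delay-corrected epochs.

    Frames inside movement bouts are excluded; an epoch whose frames are all
    masked is flagged missing.  Both a mean-dff and a transient-rate view are
    computed: dff integrates sub-threshold activity, the event rate is robust
    to slow drift.
    """
    if protocol.total_duration_s < trace.duration_s - 60.0:
        raise ValueError("protocol does not cover the trace")
    times = trace.times_s
    keep = ~movement.contains(times) if movement is not None and len(movement) else np.ones(
        times.size, bool
    )
    masks = _epoch_frame_masks(times, protocol)
    base_mask = masks[0] & keep
    if not np.any(base_mask):
        raise ValueError("baseline epoch fully masked by movement")
    baseline_med = float(np.median(trace.dff[base_mask]))
    activity = trace.dff - baseline_med

    if transients is None:
        from .calcium import detect_transients

        transients = detect_transients(trace)
    onsets = np.array([ev.onset_s for ev in transients])
    keep_onsets = (
        onsets[~movement.contains(onsets)]
        if movement is not None and len(movement) and onsets.size
        else onsets
    )

    eff = protocol.effective_epochs()
    levels = np.array([ep.co2_percent for ep in eff])
    means = np.full(levels.size, np.nan)
    rates = np.full(levels.size, np.nan)
    durs = np.zeros(levels.size)
    missing = np.zeros(levels.size, dtype=bool)
    for k, (ep, m) in enumerate(zip(eff, masks)):
        mk = m & keep
        if not np.any(mk):
            missing[k] = True
            continue
        means[k] = float(np.mean(activity[mk]))
        lo = max(ep.start_s, times[0])
        hi = min(ep.end_s, times[-1])
        durs[k] = max(hi - lo, 1e-9)
        n_ev = np.sum((keep_onsets >= lo) & (keep_onsets < hi)) if keep_onsets.size else 0
        rates[k] = float(n_ev) / durs[k]

    hyper_idx = [k for k, lvl in enumerate(levels) if lvl > 0]
    lo_idx = hyper_idx[0] if hyper_idx else None
    hi_idx = hyper_idx[-1] if hyper_idx else None
    delta_low = means[lo_idx] - means[0] if lo_idx is not None else np.nan
    delta_high = means[hi_idx] - means[0] if hi_idx is not None else np.nan

    w = max(1, int(round(smooth_s * trace.frame_rate)))
    smooth = ndimage.uniform_filter1d(np.where(keep, activity, 0.0), w, mode="nearest")
    onset_peak = np.nan
    onset_contrast = np.nan
    late = np.nan
    if lo_idx is not None and not missing[lo_idx]:
        ep = eff[lo_idx]
        onset_end = min(ep.start_s + onset_window_s, ep.end_s)
        sel = (times >= ep.start_s) & (times < onset_end)
        if np.any(sel):
            onset_peak = float(np.max(smooth[sel]))
            # contrast of the onset window against the rest of hypercapnia:
            # an adapting burst concentrates activity there, a stationary
            # process does not
            hyper_end = eff[hi_idx].end_s
            rest = (times >= onset_end) & (times < hyper_end) & keep
            if np.any(rest):
                onset_contrast = float(
                    np.mean(activity[sel & keep]) - np.mean(activity[rest])
                )
    if hi_idx is not None and not missing[hi_idx]:
        ep = eff[hi_idx]
        sel = (times >= max(ep.end_s - late_window_s, ep.start_s)) & (times < ep.end_s) & keep
        if np.any(sel):
            late = float(np.mean(activity[sel]))
    adaptation = 1.0 - late / onset_peak if onset_peak and onset_peak > 0 else np.nan

    rec_idx = levels.size - 1 if levels[-1] == 0 and levels.size > 1 else None
    recovery = means[rec_idx] if rec_idx is not None else np.nan
    recovery_rate = rates[rec_idx] if rec_idx is not None else np.nan
    base_smooth = smooth[base_mask]
    return EpochStats(
        epoch_levels=levels,
        epoch_mean_activity=means,
        epoch_rate=rates,
        epoch_duration_s=durs,
        epoch_missing=missing,
        baseline_activity=float(means[0]),
        baseline_rate=float(rates[0]) if not missing[0] else np.nan,
        delta_low=float(delta_low),
        delta_high=float(delta_high),
        onset_peak=float(onset_peak),
        onset_contrast=float(onset_contrast),
        late_activity=float(late),
        adaptation_index=float(adaptation),
        recovery_activity=float(recovery),
        recovery_rate=float(recovery_rate),
        baseline_smooth_sd=mad_sd(base_smooth),
    )


def co2_modulation_test(
    trace: CalciumTrace,
    protocol: GasProtocol,
    block_s: float = 15.0,
    n_permutations: int | None = None,
    seed: int = 0,
    guard_s: float = 60.0,
) -> float:
    """Circular-rotation test for CO2 modulation of mean activity.

    The statistic is the largest |epoch-mean minus baseline-mean| of
    activity over the hypercapnic levels, evaluated on the record up to the
    end of the last hypercapnic epoch.  The null distribution is the same
    statistic at every non-zero circular shift of the activity against the
    protocol (computed for all shifts at once by FFT cross-correlation).
    Circular shifting preserves the full autocorrelation structure of the
    activity — slow rhythms included — so the test stays calibrated for
    periodically active neurons, while the frame-level granularity keeps
    the handful of shifts that re-align the periodic protocol from limiting
    attainable significance.  Shifts within ``guard_s`` of zero are excluded
    from the null: there the activity is still nearly aligned with the true
    epochs, so they echo the observed statistic rather than sampling the
    null.  The test is deterministic; ``block_s``, ``n_permutations`` and
    ``seed`` are accepted for interface stability.
    """
    del block_s, n_permutations, seed
    times = trace.times_s
    eff = protocol.effective_epochs()
    hyper = [ep for ep in eff if ep.co2_percent > 0]
    if not hyper:
        return 1.0
    t_end = min(hyper[-1].end_s, times[-1])
    sel = times < t_end
    a = trace.dff[sel].astype(float)
    tt = times[sel]
    n = a.size
    if n < 16:
        return 1.0
    fa = np.fft.rfft(a)
    levels = sorted({ep.co2_percent for ep in eff if ep.start_s < t_end})
    means = {}
    for lvl in levels:
        u = np.zeros(n)
        for ep in eff:
            if ep.co2_percent == lvl:
                u[(tt >= ep.start_s) & (tt < ep.end_s)] = 1.0
        cnt = u.sum()
        if cnt == 0:
            continue
        # epoch mean of the shifted activity, for every circular shift
        means[lvl] = np.fft.irfft(fa * np.conj(np.fft.rfft(u)), n) / cnt
    if 0.0 not in means or len(means) < 2:
        return 1.0
    stat = np.max(
        np.abs(np.stack([means[lvl] - means[0.0] for lvl in levels if lvl > 0])),
        axis=0,
    )
    rate = n / (tt[-1] - tt[0]) if tt[-1] > tt[0] else 1.0
    g = min(int(round(guard_s * rate)), (n - 2) // 2)
    null = stat[1 + g : n - g]
    if null.size == 0:
        return 1.0
    return float((1 + np.sum(null >= stat[0])) / (1 + null.size))


def two_component(
    stats: EpochStats,
    near_origin_radius: float = 0.08,
    identity_band: float = 0.04,
) -> TwoComponentPoint:
    """Place (delta_low, delta_high) relative to the identity line.

    Region priority: near-origin (within ``near_origin_radius`` of (0,0)),
    then negative-quadrant (both deltas negative), then above-/below-identity
    by the sign of delta_high - delta_low; points within the identity band
    keep that sign-based region but are flagged ``on_band``.
    """
    dl, dh = stats.delta_low, stats.delta_high
    if not (np.isfinite(dl) and np.isfinite(dh)):
        raise ValueError("two-component analysis needs finite deltas")
    on_band = abs(dh - dl) <= identity_band
    if np.hypot(dl, dh) <= near_origin_radius:
        region = "near-origin"
    elif dl < 0 and dh < 0:
        region = "negative-quadrant"
    elif dh >= dl:
        region = "above-identity"
    else:
        region = "below-identity"
    return TwoComponentPoint(dl, dh, region, on_band)


# ---------------------------------------------------------------------------


def _event_rule(ev: Optional[EventEvidence], cfg: ClassifierConfig) -> tuple[bool, str]:
    if ev is None or ev.n_matched < cfg.event_min_matched:
        return False, f"matched events {0 if ev is None else ev.n_matched} < {cfg.event_min_matched}"
    ok = (
        ev.p_sign < cfg.event_alpha
        and cfg.event_min_median_lead_s <= ev.median_lead_s <= cfg.event_max_median_lead_s
        and ev.lead_iqr_s <= cfg.event_max_iqr_s
        and ev.pos_fraction >= cfg.event_min_pos_fraction
    )
    detail = (
        f"n={ev.n_matched}, median lead={ev.median_lead_s:.2f}s, "
        f"IQR={ev.lead_iqr_s:.2f}s, pos={ev.pos_fraction:.2f}, p={ev.p_sign:.2g}"
    )
    return ok, detail


def classify_neuron(
    stats: EpochStats,
    sniff_evidence: Optional[EventEvidence] = None,
    exp_evidence: Optional[EventEvidence] = None,
    fr_correlation: Optional[CorrelationResult] = None,
    config: Optional[ClassifierConfig] = None,
    roi_id: str = "roi",
) -> NeuronClassification:
    """Run the priority rule cascade and return the single winning label.

    ``stats.mod_p`` must be filled (see ``co2_modulation_test``) for the
    E_G/T/NC-RR rules; a NaN there is treated as "not significant".
    A neuron with a missing epoch is labelled ``unclassifiable``.
    """
    cfg = config or ClassifierConfig()
    trail: list[tuple[str, bool, str]] = []
    point: Optional[TwoComponentPoint] = None

    def done(label: str) -> NeuronClassification:
        return NeuronClassification(
            roi_id, label, stats, point, sniff_evidence, exp_evidence,
            fr_correlation, trail,
        )

    if stats.has_missing_epoch:
        trail.append(("missing-epoch", True, "epoch fully masked by movement"))
        return done("unclassifiable")
    point = two_component(stats, cfg.near_origin_radius, cfg.identity_band)

    mod_sig = np.isfinite(stats.mod_p) and stats.mod_p < cfg.mod_alpha

    fr_sig = (
        fr_correlation is not None
        and not fr_correlation.degenerate
        and np.isfinite(fr_correlation.p)
        and fr_correlation.p < cfg.fr_alpha
        and fr_correlation.r > 0
    )

    ok, detail = _event_rule(exp_evidence, cfg)
    trail.append(("Exp", ok, detail))
    if ok:
        return done("Exp")

    ok, detail = _event_rule(sniff_evidence, cfg)
    trail.append(("Sn", ok, detail))
    if ok:
        return done("Sn")

    # suppression is judged on mean activity, not detected event rate: dense
    # resting activity merges into fewer detections, compressing rate ratios,
    # while the dff mean preserves them
    hyper_act = stats.epoch_mean_activity[stats.epoch_levels > 0]
    hyper_rates = stats.epoch_rate[stats.epoch_levels > 0]
    # abrupt silencing pushes hypercapnic activity below the baseline
    # *median* (negative on this scale) in both epochs — a stationary bursty
    # neuron cannot do that, since its epoch mean always exceeds the baseline
    # median.  A deep drop is conclusive by itself; a shallow one could also
    # be a breathing-rhythm-coupled neuron whose rhythm waned under CO2, so
    # it additionally requires the absence of fR coupling.
    drop = max(cfg.inhibited_min_drop, cfg.inhibited_fraction * stats.baseline_activity)
    deep = bool(np.all(hyper_act < -cfg.inhibited_deep_drop))
    shallow = bool(np.all(hyper_act < -drop)) and not fr_sig
    ok = (
        stats.baseline_rate >= cfg.min_baseline_rate
        and hyper_act.size > 0
        and stats.baseline_activity > cfg.min_baseline_activity
        and (deep or shallow)
        and bool(np.all(hyper_rates < cfg.inhibited_rate_fraction * stats.baseline_rate))
    )
    trail.append(
        ("I", ok,
         f"baseline rate={stats.baseline_rate:.3f}/s, "
         f"baseline activity={stats.baseline_activity:.3f}, "
         f"hypercapnic activity={np.array2string(hyper_act, precision=3)}")
    )
    if ok:
        return done("I")

    onset_sig = (
        np.isfinite(stats.onset_peak)
        and stats.onset_peak
        > max(
            stats.baseline_activity
            + cfg.onset_z * max(stats.baseline_smooth_sd, 1e-6),
            cfg.onset_min_peak,
        )
    )
    # the low-rest-activity condition separates a genuine adapting burst from
    # a respiratory-rhythm neuron whose phase happens to align with the CO2
    # step: the latter is just as active at rest
    ok = (
        onset_sig
        and stats.baseline_activity < cfg.ea_max_baseline_activity
        and np.isfinite(stats.onset_contrast)
        and stats.onset_contrast > cfg.onset_min_contrast
        and np.isfinite(stats.adaptation_index)
        and stats.adaptation_index > cfg.adaptation_cutoff
        and point.region == "below-identity"
    )
    trail.append(
        ("E_A", ok,
         f"onset peak={stats.onset_peak:.3f} (sig={onset_sig}), "
         f"baseline activity={stats.baseline_activity:.3f}, "
         f"contrast={stats.onset_contrast:.3f}, "
         f"adaptation={stats.adaptation_index:.2f}, region={point.region}")
    )
    if ok:
        return done("E_A")

    recovered = (
        stats.recovery_activity
        < stats.baseline_activity
        + cfg.recovery_fraction * max(stats.delta_high, 0.0)
    )
    # the effect-size floor keeps session-level breathing imbalance (which
    # makes any fR-coupled neuron mildly epoch-aligned) out of this class
    eg_mod_sig = np.isfinite(stats.mod_p) and stats.mod_p < cfg.eg_mod_alpha
    ok = (
        stats.delta_high > stats.delta_low > 0
        and stats.delta_high >= cfg.eg_min_delta
        and eg_mod_sig
        and point.region == "above-identity"
        and recovered
    )
    trail.append(
        ("E_G", ok,
         f"deltas=({stats.delta_low:.3f}, {stats.delta_high:.3f}), "
         f"mod p={stats.mod_p:.3g}, recovered={recovered}")
    )
    if ok:
        return done("E_G")

    good = ~stats.epoch_missing & np.isfinite(stats.epoch_rate)
    overall_rate = (
        float(np.average(stats.epoch_rate[good], weights=stats.epoch_duration_s[good]))
        if np.any(good)
        else 0.0
    )
    # tonic means unmodulated by anything observed: a CO2-uniform but
    # fR-correlated neuron belongs to the respiratory-related class below
    t_mod_sig = np.isfinite(stats.mod_p) and stats.mod_p < cfg.t_mod_alpha
    ok = bool(
        overall_rate >= cfg.tonic_min_rate
        and np.all(stats.epoch_rate[good] >= cfg.tonic_uniformity * overall_rate)
        and not t_mod_sig
        and not fr_sig
    )
    trail.append(
        ("T", ok,
         f"overall rate={overall_rate:.3f}/s, "
         f"epoch rates={np.array2string(stats.epoch_rate, precision=3)}, "
         f"mod p={stats.mod_p:.3g}, fR-correlated={fr_sig}")
    )
    if ok:
        return done("T")

    # an fR-coupled neuron may test CO2-"significant" purely through session-
    # level imbalance of breathing variability across epochs; only a sizable
    # delta disqualifies it from the respiratory-related class
    max_delta = max(abs(stats.delta_low), abs(stats.delta_high))
    ok = fr_sig and (not mod_sig or max_delta < cfg.nc_rr_max_delta)
    trail.append(
        ("NC-RR", ok,
         "no fR correlation supplied" if fr_correlation is None else
         f"r={fr_correlation.r:.2f} at lag {fr_correlation.lag_s:.2f}s, "
         f"p={fr_correlation.p:.3g}, mod p={stats.mod_p:.3g}, "
         f"max|delta|={max_delta:.2f}")
    )
    if ok:
        return done("NC-RR")

    trail.append(("NC", True, "no earlier rule fired"))
    return done("NC")


def classify_population(
    neurons: Sequence[dict],
    config: Optional[ClassifierConfig] = None,
):
    """Classify a population and tabulate composition.

    ``neurons`` is a sequence of dicts with keys ``roi_id``, ``stats`` and
    optional ``sniff_evidence``, ``exp_evidence``, ``fr_correlation``.  The
    near-origin radius and identity band are scaled to the population
    (0.5x / 0.25x the robust SD of all deltas), floored at the config's
    absolute defaults.  Returns ``(classifications, table, counts)`` where
    ``table`` is a DataFrame and ``counts`` includes per-label counts,
    fractions and both accountings of the CO2-modulated fraction (with and
    without the sniff-coding class).
    """
    import pandas as pd

    cfg = config or ClassifierConfig()
    if len(neurons):
        deltas = np.concatenate(
            [[n["stats"].delta_low, n["stats"].delta_high] for n in neurons]
        )
        deltas = deltas[np.isfinite(deltas)]
        pop_sd = mad_sd(deltas) if deltas.size else 0.0
        from dataclasses import replace as dc_replace

        cfg = dc_replace(
            cfg,
            near_origin_radius=min(
                max(cfg.near_origin_radius, 0.5 * pop_sd), cfg.near_origin_radius_max
            ),
            identity_band=min(
                max(cfg.identity_band, 0.25 * pop_sd), cfg.identity_band_max
            ),
        )

    results = [
        classify_neuron(
            n["stats"],
            sniff_evidence=n.get("sniff_evidence"),
            exp_evidence=n.get("exp_evidence"),
            fr_correlation=n.get("fr_correlation"),
            config=cfg,
            roi_id=n.get("roi_id", f"roi{k:03d}"),
        )
        for k, n in enumerate(neurons)
    ]
    rows = [
        {
            "roi_id": r.roi_id,
            "label": r.label,
            "delta_low": r.point.delta_low,
            "delta_high": r.point.delta_high,
            "region": r.point.region,
            "mod_p": r.stats.mod_p,
            "baseline_rate": r.stats.baseline_rate,
            "adaptation_index": r.stats.adaptation_index,
        }
        for r in results
    ]
    table = pd.DataFrame(rows)
    classified = [r for r in results if r.label != "unclassifiable"]
    n_cls = len(classified)
    counts = {lbl: sum(r.label == lbl for r in classified) for lbl in CLASS_LABELS}
    n_mod = sum(counts[lbl] for lbl in CO2_MODULATED)
    summary = {
        "n_total": len(results),
        "n_classified": n_cls,
        "n_unclassifiable": len(results) - n_cls,
        "counts": counts,
        "fractions": {
            lbl: (counts[lbl] / n_cls if n_cls else 0.0) for lbl in CLASS_LABELS
        },
        "co2_modulated": n_mod,
        "co2_modulated_percent": 100.0 * n_mod / n_cls if n_cls else 0.0,
        # alternative accounting: sniff-coding counted as modulated
        "co2_modulated_incl_sniff": n_mod + counts["Sn"],
        "co2_modulated_incl_sniff_percent": (
            100.0 * (n_mod + counts["Sn"]) / n_cls if n_cls else 0.0
        ),
    }
    return results, table, summary


def plot_two_component(results, path=None, ax=None):
    """Scatter of (delta_low, delta_high) with the identity line and regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    palette = {
        "E_A": "tab:red", "E_G": "tab:orange", "I": "tab:blue", "T": "tab:purple",
        "Sn": "tab:pink", "Exp": "tab:brown", "NC": "tab:gray", "NC-RR": "tab:green",
        "unclassifiable": "k",
    }
    for r in results:
        ax.scatter(
            r.point.delta_low, r.point.delta_high,
            color=palette.get(r.label, "k"), s=18, label=r.label,
        )
    lim = max(
        0.1,
        1.1 * max(abs(r.point.delta_low) for r in results) if results else 0.1,
        1.1 * max(abs(r.point.delta_high) for r in results) if results else 0.1,
    )
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("activity change at lower CO2 level")
    ax.set_ylabel("activity change at higher CO2 level")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=7, loc="best")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
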