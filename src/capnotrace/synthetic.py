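"""Ground-truth-labelled synthetic recordings of breathing and Ca activity.

The generator emulates the study conditions of a freely moving mouse in a
whole-body plethysmography chamber breathing stepped CO2 (3-min epochs,
0-3-6-0% for RTN/Raphe sessions or 0-6-9-0% for pF_L sessions) while ROI
fluorescence is imaged at 10-20 frames/s:

* breathing whose frequency and tidal volume step up with the CO2 level and
  partially adapt within an epoch;
* sniff bouts (brief high-frequency, low-amplitude runs), active-expiration
  events (enlarged expiratory troughs, more frequent at higher CO2), and
  movement bouts (broadband artefactual excursions on the WBP channel);
* per-class GCaMP activity: events drawn from an inhomogeneous Poisson
  process shaped by the class template, convolved with a fast-rise /
  exponential-decay (difference-of-exponentials) kernel, riding on noise and
  slow drift.

Every trace carries exactly one ground-truth label, and a fixed seed gives a
byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._utils import child_seed
from .calcium import CalciumTrace, compute_dff
from .plethysmography import PlethysmographyTrace
from .protocol import GasProtocol

CLASS_LABELS = ("I", "E_A", "E_G", "T", "Sn", "Exp", "NC", "NC-RR")
QC_DEFECTS = ("movement_locked", "flat", "focal_drift", "no_soma")

#: per-CO2-level scaling of breathing frequency and tidal volume (partial
#: adaptation on top of these is handled by the onset overshoot)
FR_MULTIPLIERS = {0.0: 1.0, 3.0: 1.25, 6.0: 1.5, 9.0: 1.75}
VT_MULTIPLIERS = {0.0: 1.0, 3.0: 1.35, 6.0: 1.7, 9.0: 2.0}
#: active-expiration event rate (events/s) per CO2 level
EXP_RATES = {0.0: 0.02, 3.0: 0.08, 6.0: 0.25, 9.0: 0.3}
#: Ca onset lead before active expiration, per CO2 level (s)
EXP_LEADS = {6.0: 0.5, 9.0: 0.3, 3.0: 0.6, 0.0: 0.6}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated recording session."""

    protocol_levels: tuple = (0.0, 3.0, 6.0, 0.0)
    epoch_durations: tuple = (180.0, 180.0, 180.0, 180.0)
    wbp_rate: float = 100.0            # samples/s
    ca_rate: float = 15.0              # frames/s (10-20)
    seed: int = 0
    wbp_noise: float = 0.02            # fraction of baseline V_T amplitude
    ca_noise: float = 0.05             # dF/F0 SD of frame noise
    movement_rate_per_min: float = 2.0
    analyzer_delay_s: float = 17.5     # CO2 readout delay (15-20 s)
    body_mass_g: float = 25.0
    calibration_ml_per_unit: float = 1.0
    # eupneic breathing
    base_fr_bpm: float = 180.0
    base_vt_ml: float = 0.15
    fr_multipliers: dict = field(default_factory=lambda: dict(FR_MULTIPLIERS))
    vt_multipliers: dict = field(default_factory=lambda: dict(VT_MULTIPLIERS))
    onset_overshoot: float = 0.15      # transient extra drive at each CO2 step
    breath_adaptation_tau_s: float = 45.0
    fr_wander_sd: float = 0.08         # slow fractional wander of eupneic fR
    fr_wander_period_s: float = 31.0   # center period of the behavioral rhythm
    fr_wander_coherence_s: float = 15.0   # phase-coherence time of the rhythm
    cycle_jitter: float = 0.03
    vt_jitter: float = 0.05            # breath-to-breath tidal-volume variability
    insp_fraction: float = 0.35        # inspiratory share of the cycle
    insp_share: float = 0.65           # share of V_T above baseline
    # behavioral events
    sniff_rate_per_min: float = 1.5
    sniff_duration_s: tuple = (0.6, 1.2)
    sniff_fr_factor: float = 2.5
    sniff_fr_min_bpm: float = 600.0
    sniff_vt_factor: float = 0.5
    exp_rates_per_s: dict = field(default_factory=lambda: dict(EXP_RATES))
    exp_trough_factor: float = 5.0
    movement_duration_s: tuple = (0.3, 1.5)
    movement_amp_factor: float = 4.0
    # calcium
    ca_amplitude: float = 0.8          # dF/F0 per event
    ca_amplitude_jitter: float = 0.1
    kernel_rise_tau_s: float = 0.2
    kernel_decay_tau_s: float = 1.5    # GCaMP6s; 0.7 for the faster 6f variant
    ca_drift_per_min: float = 0.005    # slow baseline trend, fraction of F0
    ca_drift_sin_amplitude: float = 0.02   # slow periodic baseline wobble

    def __post_init__(self) -> None:
        if len(self.protocol_levels) != len(self.epoch_durations):
            raise ValueError("one duration per protocol level required")
        if any(d <= 0 for d in self.epoch_durations):
            raise ValueError("epoch durations must be > 0")
        if self.wbp_rate <= 0 or self.ca_rate <= 0:
            raise ValueError("sample rates must be > 0")
        for lvl, dur in zip(self.protocol_levels, self.epoch_durations):
            fr = self.base_fr_bpm * self.fr_multipliers.get(float(lvl), 1.0)
            if dur < 10 * 60.0 / fr:
                raise ValueError(
                    f"epoch at {lvl}% CO2 shorter than 10 breaths at {fr:.0f} bpm"
                )

    @property
    def total_duration_s(self) -> float:
        return float(sum(self.epoch_durations))

    def true_epoch_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.epoch_durations)])

    def protocol(self) -> GasProtocol:
        """Nominal protocol as the gas analyzer would log it.

        Transitions appear ``analyzer_delay_s`` after the true chamber
        change; the recording starts and ends inside the logged first/last
        epoch.
        """
        starts = self.true_epoch_starts()
        d = self.analyzer_delay_s
        bounds = [0.0] + [s + d for s in starts[1:-1]] + [starts[-1]]
        from .protocol import Epoch

        epochs = [
            Epoch(float(lvl), bounds[i], bounds[i + 1])
            for i, lvl in enumerate(self.protocol_levels)
        ]
        return GasProtocol(epochs, analyzer_delay_s=d)

    def level_at(self, t: float) -> float:
        starts = self.true_epoch_starts()
        k = int(np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                        len(self.protocol_levels) - 1))
        return float(self.protocol_levels[k])


@dataclass
class NeuronTemplate:
    """Parameters of one neuron's class-typical activity."""

    class_label: str
    base_rate: float = 0.06              # events/s
    epoch_rate_multipliers: Optional[dict] = None   # CO2 level -> scaling
    adaptation_tau_s: float = 20.0       # E_A burst decay
    onset_peak_rate: float = 1.5         # E_A events/s at the CO2 step
    rebound_peak_rate: float = 0.5       # E_A offset rebound
    event_lead_s: tuple | dict = (0.4, 0.8)   # Sn range, or Exp per-level dict
    event_lead_jitter_s: float = 0.05
    kernel_rise_tau_s: Optional[float] = None    # None: use config value
    kernel_decay_tau_s: Optional[float] = None
    nc_rr_gain: float = 0.3              # NC-RR: events/s per positive fR-deviation SD
    defect: Optional[str] = None         # QC defect injected into this trace

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.base_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.defect is not None and self.defect not in QC_DEFECTS:
            raise ValueError(f"unknown defect {self.defect!r}")

    @classmethod
    def for_class(cls, label: str, **overrides) -> "NeuronTemplate":
        defaults = {
            "T": dict(base_rate=0.25, epoch_rate_multipliers=None),
            "NC": dict(base_rate=0.06),
            "I": dict(base_rate=0.3,
                      epoch_rate_multipliers={0.0: 1.0, 3.0: 0.08, 6.0: 0.08, 9.0: 0.08}),
            "E_G": dict(base_rate=0.4,
                        epoch_rate_multipliers={0.0: 0.05, 3.0: 1.0, 6.0: 2.0, 9.0: 2.75}),
            "E_A": dict(base_rate=0.03),
            "Sn": dict(base_rate=0.03, event_lead_s=(0.4, 0.8)),
            "Exp": dict(base_rate=0.005, event_lead_s=dict(EXP_LEADS)),
            "NC-RR": dict(base_rate=0.01, nc_rr_gain=0.3),
        }[label]
        defaults.update(overrides)
        return cls(class_label=label, **defaults)


@dataclass
class NeuronTruth:
    roi_id: str
    class_label: str
    event_times_s: np.ndarray
    defect: Optional[str] = None
    params: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    epoch_levels: np.ndarray
    epoch_starts_s: np.ndarray           # true chamber-gas times
    breath_onsets_s: np.ndarray
    breath_fr_bpm: np.ndarray            # instantaneous, per breath
    breath_vt_ml: np.ndarray             # peak-minus-trough, mL (per animal)
    breath_is_sniff: np.ndarray
    sniff_onsets_s: np.ndarray
    sniff_durations_s: np.ndarray
    exp_onsets_s: np.ndarray             # active-expiration onsets
    movement_onsets_s: np.ndarray
    movement_durations_s: np.ndarray
    neurons: list = field(default_factory=list)   # NeuronTruth entries


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    wbp: PlethysmographyTrace
    movement_channel: np.ndarray         # same rate as the WBP trace
    traces: list                         # CalciumTrace per neuron
    protocol: GasProtocol                # nominal (analyzer-logged)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# breathing


def _draw_poisson_times(rng, rate_fn, t_end: float, min_sep: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson times by thinning against the max rate."""
    tgrid = np.linspace(0, t_end, 2049)
    rates = np.array([rate_fn(t) for t in tgrid])
    rmax = float(rates.max())
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * t_end)
    cand = np.sort(rng.uniform(0, t_end, n))
    keep = rng.uniform(0, rmax, n) < np.interp(cand, tgrid, rates)
    times = cand[keep]
    if min_sep > 0 and times.size:
        out = [times[0]]
        for t in times[1:]:
            if t - out[-1] >= min_sep:
                out.append(t)
        times = np.array(out)
    return times


def simulate_breathing(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[PlethysmographyTrace, np.ndarray, GroundTruth]:
    """Synthesize the WBP pressure trace plus the behavioral ground truth.

    Returns ``(wbp_trace, movement_channel, truth)``.  Each breath is one
    asymmetric sinusoid cycle (inspiratory hump, expiratory trough) whose
    amplitude encodes V_T; f_R and V_T step with the CO2 level and partially
    adapt within an epoch.  Sniff bouts, active-expiration breaths and
    movement bouts are injected at known (returned) times.
    """
    if rng is None:
        rng = np.random.default_rng(child_seed(config.seed, 0))
    T = config.total_duration_s
    fs = config.wbp_rate
    n = int(round(T * fs))
    samples = np.zeros(n)
    starts = config.true_epoch_starts()

    sniff_onsets = _draw_poisson_times(
        rng, lambda t: config.sniff_rate_per_min / 60.0, T - 3.0, min_sep=3.0
    )
    sniff_durs = rng.uniform(*config.sniff_duration_s, sniff_onsets.size)
    # spacing keeps consecutive Ca transients of an expiratory neuron
    # resolvable and each event's onset unambiguous in a +/-2 s window
    exp_cand = _draw_poisson_times(
        rng,
        lambda t: config.exp_rates_per_s.get(config.level_at(t), 0.0),
        T - 2.0,
        min_sep=2.2,
    )
    move_onsets = _draw_poisson_times(
        rng, lambda t: config.movement_rate_per_min / 60.0, T - 2.0, min_sep=2.0
    )
    move_durs = rng.uniform(*config.movement_duration_s, move_onsets.size)

    # drop expiration candidates inside sniff bouts: sniffing is its own event
    if exp_cand.size and sniff_onsets.size:
        in_sniff = np.zeros(exp_cand.size, bool)
        for on, du in zip(sniff_onsets, sniff_durs):
            in_sniff |= (exp_cand >= on - 0.5) & (exp_cand < on + du + 0.5)
        exp_cand = exp_cand[~in_sniff]

    b_onsets, b_fr, b_vt, b_sniff = [], [], [], []
    exp_onsets: list[float] = []
    exp_idx = 0
    # slow narrowband modulation of eupneic frequency (behavioral state):
    # an oscillation near fr_wander_period_s whose phase stays coherent only
    # for ~fr_wander_coherence_s, built as a quadrature pair of OU envelopes
    tw = np.arange(0.0, T + 2.0, 1.0)
    alpha = np.exp(-1.0 / config.fr_wander_coherence_s)
    beta = np.sqrt(1 - alpha**2)
    env = np.empty((2, tw.size))
    env[:, 0] = rng.normal(0, 1, 2)
    steps = rng.normal(0, 1, (2, tw.size - 1))
    for i in range(1, tw.size):
        env[:, i] = alpha * env[:, i - 1] + beta * steps[:, i - 1]
    omega = 2 * np.pi / config.fr_wander_period_s
    wander_series = config.fr_wander_sd * (
        env[0] * np.cos(omega * tw) + env[1] * np.sin(omega * tw)
    )

    def wander_at(tt: float) -> float:
        return float(np.interp(tt, tw, wander_series))

    t = 0.0
    while t < T - 1e-9:
        lvl = config.level_at(t)
        k = int(np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                        len(config.protocol_levels) - 1))
        tau_in_epoch = t - starts[k]
        boost = 1.0
        if lvl > 0:
            boost = 1.0 + config.onset_overshoot * np.exp(
                -tau_in_epoch / config.breath_adaptation_tau_s
            )
        fr = config.base_fr_bpm * config.fr_multipliers.get(lvl, 1.0) * boost
        vt = config.base_vt_ml * config.vt_multipliers.get(lvl, 1.0) * boost

        in_sniff = False
        for on, du in zip(sniff_onsets, sniff_durs):
            if on <= t < on + du:
                in_sniff = True
                break
        if in_sniff:
            fr_i = max(config.sniff_fr_min_bpm, config.sniff_fr_factor * fr)
            vt_i = vt * config.sniff_vt_factor
        else:
            fr_i = fr * (1.0 + np.clip(wander_at(t), -0.3, 0.3))
            vt_i = vt

        cycle = (60.0 / fr_i) * (1.0 + config.cycle_jitter * rng.normal())
        cycle = float(np.clip(cycle, 0.04, 2.0))
        vt_i = vt_i * max(1.0 + config.vt_jitter * rng.normal(), 0.3)
        if t + cycle > T:
            break
        ti = config.insp_fraction * cycle
        te = cycle - ti
        a_in = config.insp_share * vt_i
        a_ex = (1.0 - config.insp_share) * vt_i
        is_exp = (
            exp_idx < exp_cand.size
            and t <= exp_cand[exp_idx] < t + cycle
            and not in_sniff
        )
        if is_exp:
            a_ex *= config.exp_trough_factor
            exp_onsets.append(t + ti)       # post-peak zero crossing
            exp_idx += 1
        while exp_idx < exp_cand.size and exp_cand[exp_idx] < t + cycle:
            exp_idx += 1                    # at most one event per breath

        i0 = int(np.ceil(t * fs))
        i1 = min(int(np.ceil((t + cycle) * fs)), n)
        u = np.arange(i0, i1) / fs - t
        insp = u < ti
        wave = np.where(
            insp,
            a_in * np.sin(np.pi * np.clip(u, 0, ti) / ti),
            -a_ex * np.sin(np.pi * np.clip(u - ti, 0, te) / te),
        )
        samples[i0:i1] += wave

        b_onsets.append(t)
        b_fr.append(60.0 / cycle)
        b_vt.append(a_in + a_ex)
        b_sniff.append(in_sniff)
        t += cycle

    samples += rng.normal(0, config.wbp_noise * config.base_vt_ml, n)

    # re-anchor sniff-bout truth to the realized first sniff breath: breathing
    # is quantized into cycles, so the behaviorally observable onset is that
    # breath, not the drawn bout time
    b_sniff_arr = np.array(b_sniff, dtype=bool)
    b_onset_arr = np.array(b_onsets)
    first = b_sniff_arr & ~np.concatenate([[False], b_sniff_arr[:-1]])
    realized = b_onset_arr[first]
    keep_bouts, real_onsets = [], []
    for j, on in enumerate(sniff_onsets):
        cand = realized[(realized >= on) & (realized < on + sniff_durs[j])]
        if cand.size:
            keep_bouts.append(j)
            real_onsets.append(float(cand[0]))
    sniff_onsets = np.array(real_onsets)
    sniff_durs = sniff_durs[keep_bouts]

    movement = rng.normal(0, 0.02 * config.movement_amp_factor * config.base_vt_ml, n)
    for on, du in zip(move_onsets, move_durs):
        i0, i1 = int(on * fs), min(int((on + du) * fs), n)
        if i1 <= i0:
            continue
        env = np.hanning(i1 - i0)
        amp = config.movement_amp_factor * config.base_vt_ml
        samples[i0:i1] += env * rng.normal(0, amp, i1 - i0)
        movement[i0:i1] += env * rng.normal(0, amp, i1 - i0)

    wbp = PlethysmographyTrace(
        samples,
        fs,
        body_mass_g=config.body_mass_g,
        calibration_ml_per_unit=config.calibration_ml_per_unit,
    )
    truth = GroundTruth(
        epoch_levels=np.asarray(config.protocol_levels, dtype=float),
        epoch_starts_s=starts[:-1],
        breath_onsets_s=np.array(b_onsets),
        breath_fr_bpm=np.array(b_fr),
        breath_vt_ml=np.array(b_vt) * config.calibration_ml_per_unit,
        breath_is_sniff=np.array(b_sniff, dtype=bool),
        sniff_onsets_s=sniff_onsets,
        sniff_durations_s=sniff_durs,
        exp_onsets_s=np.array(exp_onsets),
        movement_onsets_s=move_onsets,
        movement_durations_s=move_durs,
    )
    return wbp, movement, truth


# ---------------------------------------------------------------------------
# calcium


def _kernel(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized to 1."""
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
    k = np.exp(-np.maximum(t, 0) / tau_d) - np.exp(-np.maximum(t, 0) / tau_r)
    return np.where(t >= 0, k / peak, 0.0)


def _class_rate(
    template: NeuronTemplate, truth: GroundTruth, config: SimulationConfig,
    tgrid: np.ndarray,
) -> np.ndarray:
    """Poisson rate on the Ca frame grid for the stochastic part of a class."""
    starts = config.true_epoch_starts()
    k_epoch = np.clip(
        np.searchsorted(starts, tgrid, side="right") - 1,
        0, len(config.protocol_levels) - 1,
    )
    lvl = np.asarray(config.protocol_levels, dtype=float)[k_epoch]
    lab = template.class_label
    if lab in ("T", "NC", "Sn", "Exp"):
        return np.full(tgrid.size, template.base_rate)
    if lab in ("I", "E_G"):
        mult = template.epoch_rate_multipliers or {}
        return template.base_rate * np.array([mult.get(l, 1.0) for l in lvl])
    if lab == "E_A":
        rate = np.full(tgrid.size, template.base_rate)
        hyper_starts = [
            starts[k] for k, l in enumerate(config.protocol_levels) if l > 0
        ]
        if hyper_starts:
            t_on = hyper_starts[0]
            dt = tgrid - t_on
            rate = rate + np.where(
                dt >= 0,
                template.onset_peak_rate * np.exp(-dt / template.adaptation_tau_s),
                0.0,
            )
            # rebound at stimulus offset (return to 0% CO2)
            k_last = max(k for k, l in enumerate(config.protocol_levels) if l > 0)
            if k_last + 1 < len(config.protocol_levels):
                t_off = starts[k_last + 1]
                dt = tgrid - t_off
                rate = rate + np.where(
                    dt >= 0,
                    template.rebound_peak_rate * np.exp(-dt / 15.0),
                    0.0,
                )
        return rate
    if lab == "NC-RR":
        # activity gated on the fast (CO2-independent) component of breathing
        # frequency: deviation of observed fR from the deterministic eupneic
        # trajectory (level multipliers plus onset-overshoot adaptation)
        fr = np.interp(tgrid, truth.breath_onsets_s, truth.breath_fr_bpm)
        boost = np.ones(tgrid.size)
        hyper = lvl > 0
        boost[hyper] = 1.0 + config.onset_overshoot * np.exp(
            -(tgrid[hyper] - starts[k_epoch[hyper]]) / config.breath_adaptation_tau_s
        )
        mult = np.array([config.fr_multipliers.get(l, 1.0) for l in lvl])
        expected = config.base_fr_bpm * mult * boost
        from ._utils import mad_sd

        from scipy import ndimage

        dev = ndimage.uniform_filter1d(
            fr / expected - 1.0, max(1, int(round(5.0 * config.ca_rate))),
            mode="nearest",
        )
        sd = mad_sd(dev) or 1.0
        # proportional coding of supra-average breathing frequency; the clip
        # keeps sniff spikes from dominating (those belong to the Sn class)
        return template.base_rate + template.nc_rr_gain * np.clip(dev / sd, 0.0, 2.0)
    raise ValueError(f"unknown class label {lab!r}")


def _event_lead(template: NeuronTemplate, level: float, rng) -> float:
    lead = template.event_lead_s
    if isinstance(lead, dict):
        mu = lead.get(level, next(iter(lead.values())))
        val = mu + template.event_lead_jitter_s * rng.normal()
    else:
        val = rng.uniform(*lead)
    return float(max(val, 0.05))


def simulate_neuron(
    template: NeuronTemplate,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    roi_id: str = "roi000",
) -> tuple[CalciumTrace, NeuronTruth]:
    """Synthesize one ROI fluorescence trace following a class template.

    Stochastic events come from an inhomogeneous Poisson process shaped by
    the class; sniff-coding and expiratory neurons additionally fire one
    event per behavioral event, leading it by the template's lead.  Events
    are convolved with the difference-of-exponentials kernel, then noise and
    slow drift are added and the trace is returned in F/F0 form (F0 from the
    baseline epoch).
    """
    if truth.breath_onsets_s.size == 0:
        raise ValueError("behavioral ground truth does not cover the protocol")
    if rng is None:
        rng = np.random.default_rng(child_seed(config.seed, 1))
    T = config.total_duration_s
    dt = 1.0 / config.ca_rate
    tgrid = np.arange(0.0, T, dt)

    if template.defect == "flat":
        events = np.empty(0)
    elif template.defect == "movement_locked":
        events = np.array(
            [on + rng.uniform(0, max(du - 0.05, 0.01))
             for on, du in zip(truth.movement_onsets_s, truth.movement_durations_s)]
        )
    else:
        rate = _class_rate(template, truth, config, tgrid)
        counts = rng.poisson(rate * dt)
        events = np.repeat(tgrid, counts) + rng.uniform(0, dt, int(counts.sum()))
        if template.class_label == "Sn":
            led = np.array(
                [on - _event_lead(template, config.level_at(on), rng)
                 for on in truth.sniff_onsets_s]
            )
            events = np.concatenate([events, led])
        elif template.class_label == "Exp":
            led = np.array(
                [on - _event_lead(template, config.level_at(on), rng)
                 for on in truth.exp_onsets_s]
            )
            events = np.concatenate([events, led])
    events = np.sort(events[(events >= 0) & (events < T - 2 * dt)])

    tau_r = template.kernel_rise_tau_s or config.kernel_rise_tau_s
    tau_d = template.kernel_decay_tau_s or config.kernel_decay_tau_s
    signal = np.zeros(tgrid.size)
    span = int(np.ceil(8 * tau_d / dt))
    for te in events:
        amp = config.ca_amplitude * max(
            1.0 + config.ca_amplitude_jitter * rng.normal(), 0.25
        )
        i0 = int(np.searchsorted(tgrid, te))
        i1 = min(i0 + span, tgrid.size)
        signal[i0:i1] += amp * _kernel(tgrid[i0:i1] - te, tau_r, tau_d)

    drift_rate = 0.10 if template.defect == "focal_drift" else config.ca_drift_per_min
    phase = rng.uniform(0, 2 * np.pi)
    drift = drift_rate * tgrid / 60.0 + config.ca_drift_sin_amplitude * np.sin(
        2 * np.pi * tgrid / 300.0 + phase
    )
    noise = rng.normal(0, config.ca_noise, tgrid.size)

    f0_true = 1000.0
    F = f0_true * (1.0 + signal + drift + noise)
    F = np.maximum(F, 1.0)
    baseline_end = config.true_epoch_starts()[1]
    meta = {"ground_truth_label": template.class_label}
    if template.defect == "no_soma":
        meta["soma_visible"] = False
    trace = compute_dff(tgrid, F, (0.0, baseline_end), roi_id=roi_id, meta=meta)
    ntruth = NeuronTruth(
        roi_id=roi_id,
        class_label=template.class_label,
        event_times_s=events,
        defect=template.defect,
        params={
            "base_rate": template.base_rate,
            "kernel_rise_tau_s": tau_r,
            "kernel_decay_tau_s": tau_d,
        },
    )
    return trace, ntruth


def simulate_population(
    composition: dict,
    config: Optional[SimulationConfig] = None,
    defects: Optional[dict] = None,
    templates: Optional[dict] = None,
) -> SyntheticDataset:
    """Generate a full session: shared behavior plus one trace per neuron.

    ``composition`` maps class label -> count (counts >= 0; total > 0).
    ``defects`` optionally maps defect name -> count; defects are assigned
    to a deterministic, seed-dependent subset of the neurons.  Per-neuron
    seeds derive from the master seed, so the whole dataset is reproducible
    and per-neuron traces are independent of the composition order.
    """
    config = config or SimulationConfig()
    if not composition:
        raise ValueError("composition must name at least one class")
    if any(v < 0 for v in composition.values()):
        raise ValueError("composition counts must be >= 0")
    labels = [lbl for lbl in composition for _ in range(composition[lbl])]
    for lbl in composition:
        if lbl not in CLASS_LABELS:
            raise ValueError(f"unknown class label {lbl!r}")

    wbp, movement, truth = simulate_breathing(
        config, np.random.default_rng(child_seed(config.seed, 0))
    )

    defect_of: dict[int, str] = {}
    if defects:
        total = sum(defects.values())
        if total > len(labels):
            raise ValueError("more defects requested than neurons")
        order = np.random.default_rng(child_seed(config.seed, 9)).permutation(len(labels))
        it = iter(order.tolist())
        for name, count in defects.items():
            if name not in QC_DEFECTS:
                raise ValueError(f"unknown defect {name!r}")
            for _ in range(count):
                defect_of[next(it)] = name

    traces = []
    for i, lbl in enumerate(labels):
        tpl = (templates or {}).get(lbl, NeuronTemplate.for_class(lbl))
        if i in defect_of:
            tpl = replace(tpl, defect=defect_of[i])
        rng = np.random.default_rng(child_seed(config.seed, 1, i))
        trace, ntruth = simulate_neuron(tpl, truth, config, rng, roi_id=f"roi{i:03d}")
        traces.append(trace)
        truth.neurons.append(ntruth)

    return SyntheticDataset(
        config=config,
        wbp=wbp,
        movement_channel=movement,
        traces=traces,
        protocol=config.protocol(),
        truth=truth,
    )
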