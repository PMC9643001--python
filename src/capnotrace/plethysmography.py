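"""Breath segmentation and ventilation metrics from whole-body plethysmography.

The whole-body plethysmography (WBP) pressure signal is calibrated to
mL-equivalents.  Tidal volume (V_T) of a breath is the signal trough at the
end of expiration subtracted from the peak during inspiration, normalized to
body weight; respiratory frequency (f_R) is reported in breaths/min; minute
ventilation is their product, V_E = V_T x f_R.

In a freely moving mouse the trace additionally carries sniff bouts
(high-frequency, low-amplitude runs), active-expiration events (enlarged
expiratory troughs recruited under hypercapnia), and large broadband
excursions that arise artefactually from body movement.  This module
segments breaths and extracts all three event types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from ._utils import mad_sd, running_median
from .protocol import GasProtocol


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PlethysmographyTrace:
    """Calibrated WBP pressure time series."""

    samples: np.ndarray          # pressure, mL-equivalent units after calibration
    rate: float                  # samples/s
    body_mass_g: float = 25.0
    calibration_ml_per_unit: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sample rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class BreathTable:
    """Per-breath features; breaths strictly ordered and non-overlapping."""

    onset_s: np.ndarray          # inspiration onset
    peak_s: np.ndarray
    peak_value: np.ndarray
    trough_s: np.ndarray
    trough_value: np.ndarray
    vt: np.ndarray               # tidal volume, mL/g by default
    cycle_s: np.ndarray          # breath cycle duration
    trough_depth: np.ndarray     # expiratory trough depth below local baseline, mL
    vt_units: str = "mL/g"

    def __len__(self) -> int:
        return self.onset_s.size

    @property
    def fr_inst(self) -> np.ndarray:
        """Instantaneous respiratory frequency per breath, breaths/min."""
        return 60.0 / self.cycle_s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": self.onset_s,
                "peak_s": self.peak_s,
                "peak_value": self.peak_value,
                "trough_s": self.trough_s,
                "trough_value": self.trough_value,
                "vt": self.vt,
                "cycle_s": self.cycle_s,
                "fr_inst_bpm": self.fr_inst,
            }
        )

    @staticmethod
    def empty() -> "BreathTable":
        z = np.empty(0)
        return BreathTable(z, z, z, z, z, z, z, z)


@dataclass
class VentilationSeries:
    """Rolling-window ventilation metrics on a uniform time grid.

    The identity ``ve == vt * fr`` holds exactly at every grid point because
    ``ve`` is stored as the product of the other two fields.
    """

    time_s: np.ndarray
    vt: np.ndarray               # mL/g
    fr: np.ndarray               # breaths/min
    window_s: float
    breaths: Optional[BreathTable] = None

    @property
    def ve(self) -> np.ndarray:
        return self.vt * self.fr

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.time_s, "vt": self.vt, "fr_bpm": self.fr, "ve": self.ve}
        )


@dataclass
class EventSeries:
    """Behavioral events of one kind: sorted onsets, durations, magnitudes."""

    kind: str                    # sniff | expiration | movement
    onsets_s: np.ndarray
    durations_s: np.ndarray
    magnitudes: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.onsets_s.size and np.any(np.diff(self.onsets_s) < 0):
            raise ValueError("event onsets must be sorted")
        if np.any(self.durations_s < 0):
            raise ValueError("event durations must be >= 0")

    def __len__(self) -> int:
        return self.onsets_s.size

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside an event interval [on, on+dur)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.size, dtype=bool)
        for on, dur in zip(self.onsets_s, self.durations_s):
            out |= (t >= on) & (t < on + dur)
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.onsets_s,
                "type": self.kind,
                "duration_s": self.durations_s,
                "magnitude": self.magnitudes,
            }
        )

    @staticmethod
    def empty(kind: str) -> "EventSeries":
        z = np.empty(0)
        return EventSeries(kind, z, z, z)


# ---------------------------------------------------------------------------
# operations


def _baseline_subtract(trace: PlethysmographyTrace, window_s: float = 2.0) -> np.ndarray:
    """Remove slow baseline (DC and drift) with a running median."""
    w = int(round(window_s * trace.rate))
    return trace.samples - running_median(trace.samples, w)


def detect_breaths(
    trace: PlethysmographyTrace,
    min_prominence: float | None = None,
    min_cycle_s: float = 0.05,
    normalize: str = "per_gram",
) -> BreathTable:
    """Segment the WBP trace into breaths via prominence-filtered extrema.

    Each breath is an inspiratory peak followed by its expiratory trough
    (the minimum before the next peak); V_T is peak minus trough, converted
    to mL by the calibration factor and normalized to body mass
    (``normalize="per_gram"``, the default) or left per animal
    (``normalize="none"``).

    The default prominence floor is a fixed fraction of the trace's central
    amplitude range, so breath segmentation is invariant under positive
    rescaling and DC offset of the signal.  A flat trace yields an empty
    table.
    """
    if normalize not in ("per_gram", "none"):
        raise ValueError("normalize must be 'per_gram' or 'none'")
    x = _baseline_subtract(trace)
    if trace.duration_s < 2 * min_cycle_s or x.size < 4:
        return BreathTable.empty()
    amp_range = float(np.percentile(x, 97.5) - np.percentile(x, 2.5))
    if amp_range <= 0:
        return BreathTable.empty()     # flat trace
    if min_prominence is None:
        min_prominence = 0.15 * amp_range
    distance = max(1, int(round(min_cycle_s * trace.rate)))
    peaks, _ = sps.find_peaks(x, prominence=min_prominence, distance=distance)
    if peaks.size < 2:
        return BreathTable.empty()

    t = trace.times
    onset_idx = np.empty(peaks.size, dtype=int)
    trough_idx = np.empty(peaks.size, dtype=int)
    for i, p in enumerate(peaks):
        # inspiration onset: last non-positive sample before the peak
        left = peaks[i - 1] if i > 0 else 0
        seg = x[left:p]
        below = np.nonzero(seg <= 0)[0]
        onset_idx[i] = left + (below[-1] if below.size else 0)
        # expiratory trough: minimum between this peak and the next
        right = peaks[i + 1] if i + 1 < peaks.size else x.size
        trough_idx[i] = p + int(np.argmin(x[p:right]))

    cycle = np.diff(t[onset_idx])
    cycle = np.append(cycle, np.median(cycle) if cycle.size else np.nan)

    scale = trace.calibration_ml_per_unit
    vt = (trace.samples[peaks] - trace.samples[trough_idx]) * scale
    depth = -x[trough_idx] * scale
    units = "mL"
    if normalize == "per_gram":
        vt = vt / trace.body_mass_g
        units = "mL/g"
    return BreathTable(
        onset_s=t[onset_idx],
        peak_s=t[peaks],
        peak_value=trace.samples[peaks],
        trough_s=t[trough_idx],
        trough_value=trace.samples[trough_idx],
        vt=vt,
        cycle_s=cycle,
        trough_depth=depth,
        vt_units=units,
    )


def compute_ventilation(
    breaths: BreathTable,
    window_s: float = 10.0,
    grid_step_s: float = 0.2,
) -> VentilationSeries:
    """Rolling-window V_T and f_R on a uniform grid; V_E is their product.

    Windowed *medians* of per-breath tidal volume and cycle duration are used
    (f_R = 60 / median cycle), so brief contaminations — movement-artefact
    pseudo-breaths, single sniff breaths — do not distort the ventilation
    estimate.  Windows with no breaths inherit the nearest breath's values.
    """
    if len(breaths) == 0:
        raise ValueError("ventilation requires at least one breath")
    if window_s < float(np.nanmax(breaths.cycle_s)):
        raise ValueError("window shorter than one breath cycle")
    t0, t1 = breaths.onset_s[0], breaths.onset_s[-1] + breaths.cycle_s[-1]
    grid = np.arange(t0, t1, grid_step_s)
    onsets = breaths.onset_s
    lo = np.searchsorted(onsets, grid - window_s / 2, side="left")
    hi = np.searchsorted(onsets, grid + window_s / 2, side="right")
    vt = np.empty(grid.size)
    fr = np.empty(grid.size)
    for k in range(grid.size):
        if hi[k] > lo[k]:
            vt[k] = np.median(breaths.vt[lo[k] : hi[k]])
            fr[k] = 60.0 / np.median(breaths.cycle_s[lo[k] : hi[k]])
        else:                               # inherit from the nearest breath
            j = min(np.searchsorted(onsets, grid[k]), len(breaths) - 1)
            vt[k] = breaths.vt[j]
            fr[k] = 60.0 / breaths.cycle_s[j]
    return VentilationSeries(grid, vt, fr, window_s, breaths=breaths)


def detect_sniff_bouts(
    vent: VentilationSeries,
    fr_threshold: float | None = None,
    min_duration_s: float = 0.5,
    threshold_factor: float = 2.0,
    eupnea_window_s: float = 30.0,
    merge_gap_s: float = 0.3,
) -> EventSeries:
    """Detect sniff bouts as maximal runs of supra-threshold breath frequency.

    The detector works on the instantaneous per-breath f_R of the underlying
    breath table.  By default the threshold is ``threshold_factor`` times a
    running eupneic median of f_R (sniffing is defined behaviorally, not by a
    fixed frequency); pass ``fr_threshold`` for an absolute cutoff.  The bout
    onset is the first supra-threshold breath.
    """
    breaths = vent.breaths
    if breaths is None or len(breaths) == 0:
        return EventSeries.empty("sniff")
    fr = breaths.fr_inst
    if fr_threshold is not None:
        thr = np.full(fr.size, float(fr_threshold))
    else:
        mean_cycle = float(np.nanmean(breaths.cycle_s))
        w = max(3, int(round(eupnea_window_s / max(mean_cycle, 1e-6))))
        thr = threshold_factor * running_median(fr, w)
    above = fr > thr
    onsets, durations, mags = [], [], []
    i = 0
    while i < fr.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < fr.size:
            if above[j + 1]:
                j += 1
            elif (breaths.onset_s[j + 1] - (breaths.onset_s[j] + breaths.cycle_s[j])
                  < merge_gap_s and j + 2 < fr.size and above[j + 2]):
                j += 2          # bridge a single sub-threshold breath in a short gap
            else:
                break
        start = breaths.onset_s[i]
        end = breaths.onset_s[j] + breaths.cycle_s[j]
        if end - start >= min_duration_s:
            onsets.append(start)
            durations.append(end - start)
            mags.append(float(np.mean(fr[i : j + 1])))
        i = j + 1
    return EventSeries("sniff", np.array(onsets), np.array(durations), np.array(mags))


def detect_active_expiration(
    trace: PlethysmographyTrace,
    breaths: BreathTable,
    trough_z_threshold: float = 4.0,
    protocol: Optional[GasProtocol] = None,
) -> EventSeries:
    """Flag breaths with enlarged expiratory troughs as active expiration.

    Eupneic trough depth itself scales with the CO2-driven rise in tidal
    volume, so the statistic is the *expiratory dominance* of each breath:
    trough depth divided by the breath's own peak-to-trough excursion.  That
    shape ratio is invariant to V_T scaling; active expiration recruits the
    expiratory muscles and pushes the trough well below its eupneic share of
    the excursion.  Each breath's ratio is compared, as a robust z-score, to
    the ratio distribution of the baseline (0% CO2) epoch; without a
    protocol the reference is the whole record, flagged as such.  The event
    onset is the post-peak zero crossing of the breath; a threshold <= 0
    degenerately flags every breath.
    """
    if len(breaths) == 0:
        return EventSeries.empty("expiration")
    vt_ml = breaths.vt.copy()
    if breaths.vt_units == "mL/g":
        vt_ml = vt_ml * trace.body_mass_g
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = np.where(vt_ml > 0, breaths.trough_depth / vt_ml, 0.0)
    whole_record = True
    ref = depth
    if protocol is not None:
        base = protocol.effective_epochs()[0]
        mask = (breaths.onset_s >= base.start_s) & (breaths.onset_s < base.end_s)
        if np.count_nonzero(mask) >= 10:
            ref = depth[mask]
            whole_record = False
    med = float(np.median(ref))
    # floor the spread estimate at 0.02: finer shape variation is below the
    # resolution of the eupneic breath-to-breath variability
    sd = max(mad_sd(ref), 0.02) if float(np.ptp(ref)) > 0 else 0.0
    z = (depth - med) / sd if sd > 0 else np.zeros_like(depth)
    flagged = z > trough_z_threshold if trough_z_threshold > 0 else np.ones(len(breaths), bool)

    x = _baseline_subtract(trace)
    t = trace.times
    onsets, durations, mags = [], [], []
    for i in np.nonzero(flagged)[0]:
        p = int(round(breaths.peak_s[i] * trace.rate))
        tr = int(round(breaths.trough_s[i] * trace.rate))
        seg = x[p : max(tr, p + 1)]
        cross = np.nonzero(seg <= 0)[0]
        onset = t[p + cross[0]] if cross.size else breaths.peak_s[i]
        end = breaths.onset_s[i] + breaths.cycle_s[i]
        onsets.append(onset)
        durations.append(max(end - onset, 0.0))
        mags.append(float(z[i]))
    order = np.argsort(onsets) if onsets else slice(None)
    return EventSeries(
        "expiration",
        np.array(onsets)[order] if onsets else np.empty(0),
        np.array(durations)[order] if onsets else np.empty(0),
        np.array(mags)[order] if onsets else np.empty(0),
        meta={"whole_record_baseline": whole_record},
    )


def movement_sonogram(
    channel: np.ndarray,
    rate: float,
    window_s: float = 0.25,
    band: tuple[float, float] = (15.0, 49.0),
    z_threshold: float = 4.0,
):
    """Short-time spectral power map plus movement-bout detection.

    Movement artefacts are broadband, so bouts are intervals where the mean
    spectral power in ``band`` exceeds a robust z-threshold of its own
    distribution over time.  The same computation applies to a WBP-derived
    channel (whose breathing energy sits below the band) and to an external
    movement channel, so the two sonograms can be cross-compared.

    Returns ``(freqs, times, power, events)``.
    """
    x = np.asarray(channel, dtype=float)
    nper = int(round(window_s * rate))
    if nper > x.size:
        raise ValueError("window longer than the record")
    freqs, times, sxx = sps.spectrogram(
        x, fs=rate, nperseg=nper, noverlap=nper // 2, detrend="constant"
    )
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise ValueError(f"band {band} outside the spectrogram frequency range")
    power = sxx[sel].mean(axis=0)
    log_p = np.log10(power + 1e-30)
    med, sd = float(np.median(log_p)), mad_sd(log_p)
    z = (log_p - med) / sd if sd > 0 else np.zeros(log_p.size)
    # hysteresis: trigger at the full threshold, extend over the bout's
    # tapering edges while power stays above half of it
    above = z > z_threshold
    extend = z > z_threshold / 2

    step = times[1] - times[0] if times.size > 1 else window_s
    onsets, durations, mags = [], [], []
    i = 0
    floor = 0
    while i < above.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while i > floor and extend[i - 1]:
            i -= 1
        while j + 1 < above.size and (above[j + 1] or extend[j + 1]):
            j += 1
        onsets.append(times[i] - step / 2)
        durations.append(times[j] - times[i] + step)
        mags.append(float(np.max(z[i : j + 1])))
        i = j + 1
        floor = j + 1
    events = EventSeries(
        "movement", np.array(onsets), np.array(durations), np.array(mags)
    )
    return freqs, times, sxx, events
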