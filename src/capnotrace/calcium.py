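"""ROI fluorescence conditioning: F/F0, background subtraction, transients, QC.

Single-wavelength miniscope recordings report raw fluorescence per ROI.  The
working representation throughout is F/F0, with F0 a low percentile of F over
the baseline (0% CO2) window, which makes every downstream statistic
invariant under multiplicative gain.  Genuine GCaMP transients have a fast
rise and an exponential fall; that shape, fit as a difference of
exponentials, backs both transient kinetics summaries and the
epoch-invariance check of indicator dynamics.

Cells enter the study only if they pass four criteria: (1) the cell's
features were clearly visible (an upstream, trace-level flag here);
(2) their signals occurred in the absence of movement or were unaffected by
it; (3) fluorescence changed relative to the background; (4) the focal plane
remained constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, optimize, stats

from ._utils import MAD_TO_SD, mad_sd, running_median
from .plethysmography import EventSeries


@dataclass
class CalciumTrace:
    """Per-ROI fluorescence with its F0 and F/F0 representation."""

    roi_id: str
    times_s: np.ndarray
    F: np.ndarray                # raw fluorescence, a.u.
    F0: float                    # baseline fluorescence, a.u.
    dff: np.ndarray              # F / F0, dimensionless
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.F0 <= 0:
            raise ValueError("F0 must be > 0")
        if self.times_s.size != self.F.size or self.F.size != self.dff.size:
            raise ValueError("times, F and dff must have equal length")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times_s)))

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if self.times_s.size else 0.0


@dataclass
class TransientEvent:
    """One detected Ca transient; kinetics fields filled in by fitting."""

    onset_s: float
    peak_s: float
    amplitude: float             # dF/F0 above the running baseline
    rise_time_s: float = np.nan  # 10-90% rise
    decay_tau_s: float = np.nan
    gof: float = np.nan          # R^2 of the kinetics fit
    fit_converged: bool = False


@dataclass
class QCResult:
    eligible: bool
    criteria: dict               # {1: bool, 2: bool, 3: bool, 4: bool}
    reasons: list

    def __post_init__(self) -> None:
        assert self.eligible == all(self.criteria.values())


# ---------------------------------------------------------------------------


def compute_dff(
    times_s: np.ndarray,
    F: np.ndarray,
    baseline_window: tuple[float, float],
    roi_id: str = "roi",
    percentile: float = 10.0,
    meta: Optional[dict] = None,
) -> CalciumTrace:
    """Build the F/F0 representation of a raw fluorescence trace.

    F0 is the ``percentile``-th percentile of F over the baseline window
    (robust to transients occurring there); dff = F / F0 is unchanged when F
    is scaled by any positive gain.
    """
    times_s = np.asarray(times_s, dtype=float)
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("F contains non-finite values")
    lo, hi = baseline_window
    if lo < times_s[0] - 1e-9 or hi > times_s[-1] + 1e-9 or hi <= lo:
        raise ValueError("baseline window must lie inside the record")
    sel = (times_s >= lo) & (times_s < hi)
    f0 = float(np.percentile(F[sel], percentile))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0:g} is not positive")
    return CalciumTrace(roi_id, times_s, F, f0, F / f0, dict(meta or {}))


def subtract_background(
    roi: CalciumTrace,
    background: CalciumTrace,
    z_threshold: float = 3.0,
) -> CalciumTrace:
    """Remove a shared movement artefact using a null (background) ROI.

    A second ROI drawn over a non-fluorescent landmark (e.g. a blood-vessel
    border) carries the movement artefact but no Ca signal.  Its dff,
    scaled by a least-squares fit over the ROI's non-event frames, is
    subtracted from the ROI dff; the result keeps the ROI's non-event mean
    and carries a provenance flag.

    The fit is two-pass: a first regression over all frames (Ca transients
    are uncorrelated with the background, so the slope is nearly unbiased)
    yields a preliminary corrected trace on which transients are detected
    without the artefact masquerading as events; the final slope is then
    re-fit over the transient-free frames.
    """
    if roi.times_s.size != background.times_s.size or not np.allclose(
        roi.times_s, background.times_s
    ):
        raise ValueError("ROI and background must share the same frame grid")
    bg = background.dff

    def _fit(mask: np.ndarray) -> float:
        bg_c = bg[mask] - bg[mask].mean()
        denom = float(bg_c @ bg_c)
        if denom <= 0:
            return 0.0
        return float((roi.dff[mask] - roi.dff[mask].mean()) @ bg_c) / denom

    mask = np.ones(roi.dff.size, dtype=bool)
    scale = _fit(mask)
    prelim = replace(roi, dff=roi.dff - scale * (bg - bg.mean()))
    for ev in detect_transients(prelim, z_threshold=z_threshold):
        mask &= ~((roi.times_s >= ev.onset_s) & (roi.times_s <= ev.peak_s + 5.0))
    if np.count_nonzero(mask) >= 10:
        scale = _fit(mask)
    corrected = roi.dff - scale * (bg - bg[mask].mean())
    meta = dict(roi.meta)
    meta.update(background_subtracted=True, background_scale=scale)
    return replace(roi, dff=corrected, meta=meta)


def detect_transients(
    trace: CalciumTrace,
    z_threshold: float = 3.0,
    baseline_window_s: float = 30.0,
    merge_gap_s: float = 0.2,
    min_width_s: float = 0.34,
) -> list[TransientEvent]:
    """Detect Ca transients as robust-z excursions above a running baseline.

    The baseline is a running 20th percentile (a median would ride up on
    tonically active cells whose transients occupy much of the record), and
    the noise scale is estimated from frame-to-frame first differences,
    which sparse transients barely touch.  A detection must stay above
    threshold for at least ``min_width_s``: GCaMP decay keeps genuine
    transients supra-threshold for a large multiple of that, whereas white-
    noise crossings last one or two frames.  The onset is the last
    sub-threshold frame before the crossing.  Above-threshold runs separated
    by less than ``merge_gap_s`` are merged, so two events closer than the
    indicator decay merge into a single detection.
    """
    dff = trace.dff
    n = dff.size
    if n < 4:
        return []
    w = max(3, int(round(baseline_window_s * trace.frame_rate)))
    base = ndimage.percentile_filter(dff, 20, size=w, mode="reflect")
    resid = dff - base
    # robust white-noise SD from first differences: sd(diff) = sqrt(2) * sd;
    # on an (idealized) noise-free trace most diffs are exactly zero, so fall
    # back to an upper quantile before concluding the trace is flat
    diffs = np.abs(np.diff(dff))
    sigma = MAD_TO_SD * float(np.median(diffs)) / np.sqrt(2.0)
    if sigma <= 0:
        sigma = MAD_TO_SD * float(np.percentile(diffs, 75)) / np.sqrt(2.0)
    if sigma <= 0:
        return []
    above = resid > z_threshold * sigma
    gap = int(round(merge_gap_s * trace.frame_rate))
    min_width = max(1, int(round(min_width_s * trace.frame_rate)))

    events: list[TransientEvent] = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            if above[j + 1]:
                j += 1
            else:
                nxt = np.argmax(above[j + 1 : j + 2 + gap]) if j + 1 + gap < n else 0
                if above[j + 1 : j + 2 + gap].any():
                    j = j + 1 + int(nxt)
                else:
                    break
        if int(np.sum(above[i : j + 1])) >= min_width:
            onset_idx = max(i - 1, 0)
            peak_idx = i + int(np.argmax(dff[i : j + 1]))
            events.append(
                TransientEvent(
                    onset_s=float(trace.times_s[onset_idx]),
                    peak_s=float(trace.times_s[peak_idx]),
                    amplitude=float(resid[peak_idx]),
                )
            )
        i = j + 1
    return events


def _doe(t, t0, amp, tau_r, tau_d, base):
    """Difference-of-exponentials transient, zero before onset."""
    dt = np.maximum(t - t0, 0.0)
    k = np.exp(-dt / tau_d) - np.exp(-dt / tau_r)
    return base + amp * np.where(t >= t0, k, 0.0)


def fit_transient_kinetics(
    trace: CalciumTrace,
    event: TransientEvent,
    fit_window_s: float | None = None,
) -> TransientEvent:
    """Fit one transient's kinetics: 10-90% rise time and decay tau.

    The whole event window is fit with a difference-of-exponentials model
    (fast rise, exponential fall); the decay tau is read off directly and the
    10-90% rise time is evaluated on the fitted curve.  A non-convergent fit
    is returned flagged (``fit_converged=False``) so it can be excluded from
    kinetics summaries.
    """
    t, dff = trace.times_s, trace.dff
    if fit_window_s is None:
        fit_window_s = 8.0
    sel = (t >= event.onset_s - 1.0) & (t <= event.peak_s + fit_window_s)
    ts, ys = t[sel], dff[sel]
    if ts.size < 6:
        return replace(event, fit_converged=False)
    base0 = float(np.percentile(ys, 10))
    p0 = [event.onset_s, max(event.amplitude * 1.3, 1e-3), 0.15, 1.0, base0]
    lb = [event.onset_s - 1.0, 1e-4, 1e-3, 5e-3, base0 - 5 * abs(base0) - 1]
    ub = [event.peak_s, 100.0, 5.0, 60.0, base0 + 5 * abs(base0) + 1]
    try:
        popt, _ = optimize.curve_fit(
            _doe, ts, ys, p0=p0, bounds=(lb, ub), maxfev=5000
        )
    except (RuntimeError, ValueError):
        return replace(event, fit_converged=False)
    t0, amp, tau_r, tau_d, base = popt
    if tau_d < tau_r:               # label the slower exponential as the decay
        tau_r, tau_d = tau_d, tau_r
    fine = np.linspace(0, 10 * tau_d, 4000)
    k = np.exp(-fine / tau_d) - np.exp(-fine / tau_r)
    k /= k.max()
    ipk = int(np.argmax(k))
    t10 = fine[np.searchsorted(k[: ipk + 1], 0.1)]
    t90 = fine[np.searchsorted(k[: ipk + 1], 0.9)]
    resid = ys - _doe(ts, *popt)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return replace(
        event,
        rise_time_s=float(t90 - t10),
        decay_tau_s=float(tau_d),
        gof=r2,
        fit_converged=True,
    )


def focal_drift_metric(trace: CalciumTrace) -> float:
    """Slow baseline trend of F, as |fractional change of F0 per minute|.

    A proxy for focal-plane stability: a constant focal plane keeps the
    baseline fluorescence flat, while a drifting plane produces a sustained
    monotonic trend.
    """
    minutes = (trace.times_s - trace.times_s[0]) / 60.0
    base = running_median(trace.F, int(round(30.0 * trace.frame_rate)))
    slope = float(np.polyfit(minutes, base, 1)[0])
    return abs(slope) / trace.F0


def qc_cell(
    trace: CalciumTrace,
    movement: EventSeries,
    focal_drift: float | None = None,
    z_threshold: float = 3.0,
    movement_frac_threshold: float = 0.5,
    fisher_alpha: float = 0.01,
    drift_threshold_per_min: float = 0.05,
) -> QCResult:
    """Apply the four inclusion criteria to one ROI trace.

    1. Cell features visible — an upstream flag carried in ``trace.meta``
       (``soma_visible``, default True): morphology is judged on the movie,
       before this pipeline.
    2. Signals unaffected by movement — fails when detected transients are
       conditionally dependent on movement bouts (Fisher exact test on a 2x2
       second-bins x transient table) and the fraction of transient onsets
       inside bouts exceeds ``movement_frac_threshold``, or when transients
       occur exclusively inside bouts.
    3. Fluorescence changed relative to background — fails when no transient
       exceeds the robust z-threshold.
    4. Focal plane constant — fails when the slow baseline trend exceeds
       ``drift_threshold_per_min`` (fraction of F0 per minute).
    """
    reasons: list[str] = []
    c1 = bool(trace.meta.get("soma_visible", True))
    if not c1:
        reasons.append("criterion 1: cell features not clearly visible")

    transients = detect_transients(trace, z_threshold=z_threshold)
    c3 = len(transients) > 0
    if not c3:
        reasons.append("criterion 3: no fluorescence change relative to background")

    c2 = True
    if transients and len(movement) > 0:
        onsets = np.array([ev.onset_s for ev in transients])
        inside = movement.contains(onsets)
        frac_inside = float(np.mean(inside))
        n_out = int(np.count_nonzero(~inside))
        # 1-s bins: movement-bout occupancy vs transient occurrence
        edges = np.arange(trace.times_s[0], trace.times_s[-1] + 1.0, 1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        bout_bin = movement.contains(centers)
        has_onset = np.histogram(onsets, bins=edges)[0] > 0
        table = [
            [int(np.sum(bout_bin & has_onset)), int(np.sum(bout_bin & ~has_onset))],
            [int(np.sum(~bout_bin & has_onset)), int(np.sum(~bout_bin & ~has_onset))],
        ]
        p = stats.fisher_exact(table, alternative="greater")[1]
        if (frac_inside >= movement_frac_threshold and p < fisher_alpha) or (
            n_out == 0 and len(transients) >= 3
        ):
            c2 = False
            reasons.append(
                f"criterion 2: transients movement-locked "
                f"(fraction inside bouts {frac_inside:.2f}, Fisher p={p:.2g})"
            )

    drift = focal_drift_metric(trace) if focal_drift is None else float(focal_drift)
    c4 = drift <= drift_threshold_per_min
    if not c4:
        reasons.append(
            f"criterion 4: focal drift {drift * 100:.1f}%/min exceeds "
            f"{drift_threshold_per_min * 100:.0f}%/min"
        )

    criteria = {1: c1, 2: c2, 3: c3, 4: c4}
    return QCResult(all(criteria.values()), criteria, reasons)
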