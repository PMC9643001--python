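# Methods

This note documents the models and procedures behind `capnotrace`: what the
synthetic-recording generator emulates, how each detector and statistic is
defined, which thresholds matter and why they default to what they do, and
what the package deliberately does not claim.

## Recording model

A session is a whole-body plethysmography (WBP) pressure trace plus per-ROI
GCaMP6 fluorescence sampled at 10–20 frames/s, under a stepped-CO₂ protocol
of 3-minute epochs (0→3→6→0 % for RTN/Raphe preparations, 0→6→9→0 % for the
lateral parafacial preparation). The gas analyzer samples the chamber inflow
and reports concentration with a readout delay of roughly 15–20 s
(default 17.5 s); epoch onsets logged from the analyzer channel therefore
lag the true chamber change, and every epoch-aligned statistic uses the
delay-corrected ("effective") epochs. Times are seconds from recording
start; intervals are half-open `[start, end)`.

## Synthetic data generator

The generator exists so that every stage of the analysis can be validated
against known ground truth; its defaults are the study conditions described
above plus physiological magnitudes chosen once:

* **Breathing.** One asymmetric sinusoid cycle per breath (inspiratory hump,
  35 % of the cycle; expiratory trough carrying 35 % of the excursion),
  amplitude encoding V_T. Eupneic defaults: f_R = 180 breaths·min⁻¹ and
  V_T = 0.15 mL for a 25 g mouse. Per-level multipliers
  (f_R ×1.25/×1.5/×1.75 and V_T ×1.35/×1.7/×2.0 at 3/6/9 % CO₂) with a 15 %
  onset overshoot decaying with τ = 45 s reproduce the partial adaptation of
  the ventilatory response within an epoch. Breath-to-breath variability:
  3 % cycle jitter and 5 % V_T jitter.
* **Breathing-frequency rhythm.** Eupneic f_R is additionally modulated by a
  narrowband stochastic rhythm (center period 31 s, phase-coherence time
  15 s, SD 8 %), built as a quadrature pair of Ornstein–Uhlenbeck envelopes
  on an oscillator. The band matters: it is slow enough to survive the
  10-s rolling-median ventilation estimate, fast enough to be separable from
  the 3-minute epoch structure, and its finite coherence keeps
  circular-shift nulls valid (a strictly periodic rhythm would make
  phase-locking statistically unidentifiable, because shifting by whole
  periods reproduces it).
* **Behavioral events.** Sniff bouts (Poisson, 1.5 min⁻¹; 0.6–1.2 s;
  f_R raised to ≥ 2.5× eupnea, V_T halved), active-expiration breaths
  (per-level Poisson rates 0.02/0.08/0.25/0.3 s⁻¹ at 0/3/6/9 % CO₂, spaced
  ≥ 2.2 s so consecutive Ca²⁺ transients of an expiratory neuron stay
  resolvable; expiratory trough enlarged 5×), and movement bouts (2 min⁻¹,
  0.3–1.5 s, broadband excursions at 4× the eupneic amplitude on the WBP
  channel and on a separate movement channel). Sniff-bout ground truth is
  anchored to the realized first sniff breath, since breathing quantizes the
  behaviorally observable onset into cycles. No quantitative sniff
  frequency or expiration amplitude is established for these conditions;
  these defaults are configurable and documented, not claimed as measured
  values.
* **Calcium.** Each neuron draws event times from an inhomogeneous Poisson
  process shaped by its class template and convolves them with a
  peak-normalized difference-of-exponentials kernel (rise τ 0.2 s; decay τ
  1.5 s for the slow indicator variant, 0.7 s for the fast one), amplitude
  0.8 ΔF/F₀ with 10 % jitter, on top of frame noise (SD 0.05) and slow
  drift (0.5 %/min linear plus a 2 % sinusoid). Class templates: adapting
  neurons burst at the first CO₂ step (peak 1.5 s⁻¹ decaying with τ = 20 s)
  and rebound at washout; graded neurons scale with the level
  (0.02/0.4/0.8 s⁻¹); inhibited neurons fall from 0.3 s⁻¹ to 8 % of it;
  tonic 0.25 s⁻¹ throughout; non-coders 0.06 s⁻¹; sniff-coding and
  expiratory neurons fire one event per behavioral event, leading it by
  0.4–0.8 s (uniform, per bout) and 0.5/0.3 s (6/9 % CO₂) respectively;
  respiratory-related neurons fire in proportion to the positive part of
  the f_R rhythm deviation (clipped at 2 SD so sniff spikes do not
  dominate — sniff locking belongs to the sniff-coding class).
* **QC defects** can be injected for validation: movement-locked events,
  flat (event-free) traces, an exaggerated 10 %/min focal drift, or a
  cleared morphology flag.

A single master seed fans out through `numpy.random.SeedSequence` to the
session and to each neuron, so datasets are bit-reproducible and a neuron's
trace does not depend on the rest of the composition.

What the generator does **not** emulate: pixel-level movies and optics,
indicator nonlinearity and saturation, correlated (shared) neural noise,
breathing–cardiac coupling, and real movement artefacts' coupling into the
fluorescence channel beyond the explicit movement-locked defect (the
single-wavelength control experiments motivate treating clean traces as
movement-free). Passing tests therefore demonstrate that the pipeline's
logic and statistics recover the structure this model generates; they bound,
but do not measure, performance on real recordings.

## Detectors and statistics

* **Breaths**: prominence-filtered peaks with enforced peak/trough
  alternation; the default prominence floor is 15 % of the trace's central
  amplitude range, making segmentation invariant under gain and DC offset.
  V_T per breath is peak minus trough, calibrated and normalized per gram
  (per-animal units are available; "normalized to body weight" is read as
  per gram by default).
* **Ventilation**: rolling-window (10 s) *medians* of per-breath V_T and
  cycle duration on a 0.2-s grid — medians so that movement pseudo-breaths
  and single sniffs cannot distort the estimate; V_E is stored as the exact
  product.
* **Sniff bouts**: maximal runs of instantaneous per-breath f_R above 2× a
  running eupneic median, lasting ≥ 0.5 s. Sniffing is defined behaviorally,
  not by a fixed frequency, hence the adaptive threshold.
* **Active expiration**: the statistic is expiratory dominance — trough
  depth divided by the breath's own excursion — which cancels the
  CO₂-driven V_T scaling exactly; a breath is flagged when its ratio
  exceeds the baseline-epoch distribution by 4 robust SD (MAD floored at
  0.02, the resolution of eupneic shape variability). The event onset is
  the post-peak zero crossing.
* **Movement**: short-time spectral power (0.25-s windows) in a 15–49 Hz
  band, robust z > 4 with hysteresis down to z/2 to capture bout edges.
  Behavioral events whose onsets fall inside movement bouts are discarded
  as artefactual before any downstream use.
* **Transients**: excursions of dff above a running 20th-percentile
  baseline (30 s) by 3× a noise SD estimated from frame-to-frame first
  differences; a detection must hold ≥ 0.34 s above threshold (GCaMP decay
  keeps real transients up for seconds; white-noise crossings last a frame
  or two). Events closer than the decay merge into one detection — event
  *rates* are therefore compressed for dense firing, which is why the
  classifier judges suppression and elevation on mean dff, not on detected
  rates, wherever ratios matter.
* **Kinetics**: the whole event window is fit with the
  difference-of-exponentials model; decay τ is read off the fit and the
  10–90 % rise time is evaluated on the fitted curve; non-convergent fits
  are flagged and excluded from summaries.
* **QC**: (1) morphology is an upstream flag carried in trace metadata;
  (2) movement independence fails when transient onsets are conditionally
  dependent on movement bouts (Fisher exact test on 1-s bins at α = 0.01
  with ≥ 50 % of onsets inside bouts, or all onsets inside); (3) fails
  when no transient exceeds threshold; (4) fails when the slow baseline
  trend exceeds 5 % of F₀ per minute.
* **CO₂ modulation**: the statistic is the largest |epoch mean − baseline
  mean| of activity; the null evaluates it at every frame-level circular
  shift of the activity against the protocol (via FFT cross-correlation),
  excluding a ±60 s guard band around zero shift where the activity is
  still nearly aligned with the true epochs. Circular shifts preserve the
  full autocorrelation structure, so the test stays calibrated for
  rhythmically active neurons; block permutation does not (neighbouring
  blocks are correlated), and block-level rotation cannot resolve p-values
  below the number of blocks.
* **Respiratory-relatedness**: the session's f_R series is first stripped
  of its CO₂ response by fitting each epoch with a step plus exponential
  onset transient (a linear model; a running-median detrend phase-distorts
  slow rhythms), winsorized at 3 robust SD, and zeroed for 60 s after each
  epoch boundary where CO₂-driven and spontaneous changes are inseparable.
  The evidence statistic is the mean residual at the neuron's event times
  (at a 0.25-s lead), with a circular-shift null of the whole event train:
  spread trains get tight nulls, clustered trains wide ones, so the test
  self-calibrates to burstiness. This is far more sensitive for sparse
  point processes than a linear correlation of the traces.
* **Latency**: for each behavioral event, the nearest detected Ca²⁺ onset
  within ±2 s; lead = event onset − Ca onset, positive when the neuron
  precedes the event; histograms use 0.1-s bins; the sign test is one-sided
  for positive leads. The estimator's bias is within 0.1 s for true leads
  of 0.2–1.0 s at default noise (verified in the suite).
* **Ca–ventilation correlation**: both series winsorized at 3 robust SD,
  optionally running-median detrended; circular cross-correlation by FFT
  over ±5 s of lags; the permutation null reads the same max-|r|-in-window
  statistic at random circular shifts.

## The classifier

Rules are evaluated in a fixed priority order — Exp, Sn, I, E_A, E_G, T,
NC-RR, NC — behavioral-event classes first because their evidence is
time-locked and specific; each neuron receives exactly one label, with the
full decision trail recorded. A neuron with an epoch fully lost to movement
is `unclassifiable` and excluded from composition counts. Thresholds (all
in `ClassifierConfig`, defaults in parentheses):

* **Exp / Sn**: ≥ 8 matched events, one-sided sign test p < 0.002, median
  lead in [0.1, 1.5] s, lead IQR ≤ 0.6 s, ≥ 70 % positive leads. The
  battery is deliberately strict: with ~50 candidate events per session a
  plain α = 0.05 sign test would hand out spurious event-locked labels
  across a ~100-neuron population.
* **I** ("greatly reduced"): active at rest (≥ 0.05 detected events/s and
  baseline activity above 0.02 ΔF/F₀), hypercapnic mean activity below the
  baseline *median* in both epochs — a stationary bursty neuron cannot
  manage that, because its epoch mean always exceeds the baseline median —
  by at least 0.06 ΔF/F₀, or by at least max(0.04, 0.2× baseline activity)
  if additionally free of f_R coupling (a rhythm-coupled neuron whose
  rhythm wanes under CO₂ can mimic a shallow drop); detected rates drop
  below 75 % of baseline as corroboration.
* **E_A**: significant onset burst in the first 60 s of hypercapnia
  (smoothed activity above baseline by 3 robust SD and ≥ 0.25 ΔF/F₀
  absolute), onset-window contrast ≥ 0.25 over the rest of hypercapnia
  (separates a genuine burst from stationary activity whose rhythm phase
  happens to align with the step), low activity at rest (< 0.12 ΔF/F₀, per
  the class definition), adaptation index 1 − late/peak > 0.5 over a 60-s
  onset window, and a below-identity two-component position. Offset rebound
  is typical but not required.
* **E_G**: ΔA_high > ΔA_low > 0 with ΔA_high ≥ 0.5 ΔF/F₀, shift-test
  p < 0.05, above-identity position, and recovery back toward baseline.
  The effect-size floor keeps session-level breathing imbalance — which
  makes any f_R-coupled neuron mildly epoch-aligned — out of this class.
* **T**: overall detected rate ≥ 0.09 events/s with every epoch ≥ 40 % of
  it, no CO₂ modulation at the *strict* α = 0.01 (tonic is the default
  explanation of uniform firing; weak evidence should not strip it), and no
  f_R coupling (a CO₂-uniform but breathing-locked neuron belongs below).
* **NC-RR**: f_R-coupling p < 0.05 with positive effect, and either no CO₂
  modulation or a modulation effect below 0.5 ΔF/F₀ (see E_G above).
* **Two-component geometry**: near-origin radius ε and identity band δ
  default to 0.12 and 0.04 ΔF/F₀, scaled up to 0.5× / 0.25× the population
  robust SD of the Δ values but floored and capped (0.12–0.16 / 0.04–0.075):
  in a responder-dominated population an uncapped population scale would
  swallow genuine adapting responses into the near-origin region, and in a
  non-coder-dominated one an unfloored scale collapses to the noise floor.
  ε is set where the intrinsic spread of non-coder Δ values (≈ 0.05 ΔF/F₀
  per axis from sporadic-event sampling) leaves ≥ 90 % of them inside.

The composition summary reports the CO₂-modulated count both ways — the
strict accounting (E_A + E_G + I) and one that additionally counts
sniff-coding neurons — because whether sniff neurons count as CO₂-modulated
is ambiguous in the source accounting (the stated modulated total exceeds
E_A + E_G + I there); the package reports both rather than guessing.

## Problem sizes and numerical choices

Recovery experiments run at the study scales: 98-neuron RTN and 26-neuron
Raphe sessions (12 min each at 15 frames/s), 20 expiratory pF_L neurons at
20 frames/s with the fast kernel, sniff sessions with the bout rate raised
to 6 min⁻¹ so one session yields ≥ 50 bouts, and a 194-trace QC pool with
50 defective traces. A full RTN session simulates and analyzes in a few
seconds on one core. Permutation and shift tests are seeded from the run's
master seed; the CO₂ shift test is fully deterministic. Degenerate inputs
are contracts, not crashes: flat WBP traces yield empty breath tables,
constant series yield flagged degenerate correlations, empty compositions
yield zero-count reports.

## Known limitations

* The classifier's thresholds are tuned to the generator's effect sizes
  (they are all exposed in `ClassifierConfig`); real recordings with much
  weaker responses would need them revisited against manual labels.
* Event-rate estimates are biased low for dense firing (merging); the
  pipeline works around this rather than deconvolving, in keeping with
  treating Ca²⁺ as an imprecise proxy of firing rather than inverting it.
* Session-level imbalance of the breathing rhythm across epochs genuinely
  confounds weak CO₂ responses with respiratory-relatedness; the
  effect-size gates above resolve the generated regime, but borderline real
  neurons would remain ambiguous — as they are for human raters.
* The latency analysis reports lead/lag sign and magnitude only; it makes
  no causal claim.
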