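# capnotrace

Analysis of brainstem chemosensory neuronal activity in freely moving mice:
from paired miniscope calcium (GCaMP6) ROI traces and whole-body
plethysmography (WBP) recordings during stepped hypercapnia to ventilation
metrics, signal quality control, eight-class neuronal response
classification, and event-triggered latency analysis. A ground-truth-labelled
synthetic-recording generator makes every stage of the pipeline verifiable
end to end.

It is written for respiratory neurophysiologists working with in vivo
endoscopic Ca²⁺ imaging of chemosensory nuclei — the retrotrapezoid nucleus
(RTN), the rostral medullary raphe, and the lateral parafacial region
(pF_L) — during CO₂ challenges, and for methodologists who need a tested,
reproducible reference implementation of this analysis.

## The analysis

A session pairs a calibrated WBP pressure trace with per-ROI fluorescence
(10–20 frames/s) while inspired CO₂ steps through 3-minute epochs
(0→3→6→0 % for RTN/Raphe, 0→6→9→0 % for pF_L; the gas analyzer reads out
with a ~15–20 s delay that is corrected before any epoch statistic).

**Plethysmography.** Breaths are segmented by prominence-filtered peak/trough
detection. Tidal volume is the peak-minus-trough excursion, calibrated to mL
and normalized to body weight (V_T, mL·g⁻¹); respiratory frequency f_R is in
breaths·min⁻¹; minute ventilation is V_E = V_T × f_R, an identity that holds
exactly at every point of the rolling ventilation series. Sniff bouts
(f_R above twice the running eupneic median), active-expiration events
(expiratory trough deepened relative to the breath's own excursion), and
movement artefacts (broadband spectral power, the "sonogram") are extracted
as event series.

**Calcium.** Traces are used as F/F₀ with F₀ a low percentile of the
baseline-epoch fluorescence, so everything downstream is invariant under
detector gain. Transients (fast rise, exponential fall) are detected as
robust-z excursions over a running-percentile baseline; kinetics are fit
with a difference-of-exponentials model. Movement-locked artefacts can be
removed by regressing out a null background ROI. Cells enter the study only
if they pass four criteria: visible morphology, movement independence,
fluorescence change over background, and a stable focal plane.

**Classification.** Each eligible neuron gets exactly one of eight labels,
through a fixed-priority rule cascade backed by seeded permutation tests:

| label | meaning |
|---|---|
| `Exp` | activity time-locked to, and preceding, active expiration |
| `Sn`  | activity time-locked to, and preceding, sniff bouts |
| `I`   | active at rest, silenced at both hypercapnic levels |
| `E_A` | excited-adapting: a burst at the CO₂ step that decays (often with an offset rebound) |
| `E_G` | excited-graded: activity scales with the CO₂ level, returns to baseline on washout |
| `T`   | tonic: active throughout, unmodulated |
| `NC-RR` | no CO₂ coding, but correlated with breathing-frequency variability |
| `NC`  | none of the above |

The two-component analysis — the activity change at the higher CO₂ level
(ΔA₆) against the change at the lower level (ΔA₃), relative to the identity
line — separates adapting (below identity) from graded (above identity)
responders, places inhibited cells in the negative quadrant and non-coders
near the origin.

**Event analysis.** Event-triggered averages, per-event onset leads
(positive lead = Ca²⁺ precedes the behavioral event), and lagged
Ca–ventilation correlations with circular-shift permutation nulls.

## Worked example

Simulate a small labelled session and analyze it from the shell:

```
capnotrace simulate --composition "E_A=2,E_G=1,I=1,NC=2" --seed 11 --out demo/data
capnotrace analyze --input demo/data --seed 11 --out demo/run
```

The report (abridged) prints:

```json
{
 "composition": {
  "co2_modulated": 4,
  "co2_modulated_percent": 66.66666666666667,
  "counts": {"E_A": 2, "E_G": 1, "Exp": 0, "I": 1, "NC": 2,
             "NC-RR": 0, "Sn": 0, "T": 0},
  "n_classified": 6, "n_total": 6, "n_unclassifiable": 0
 },
 "n_candidates": 6,
 "n_eligible": 6,
 "qc_failures_by_criterion": {"1": 0, "2": 0, "3": 0, "4": 0},
 "seed": 11,
 "version": "0.1.0"
}
```

All six simulated neurons pass the four QC criteria (`n_eligible = 6`), and
the classifier recovers the generated composition exactly: both adapting
neurons, the graded one, the inhibited one, and the two non-coders; 4/6
(66.7 %) carry a CO₂-modulated label. `demo/run/` additionally holds the
breath table, ventilation series, detected behavioral events, the per-ROI QC
table, the classification table with the (ΔA₃, ΔA₆) coordinates, and the
two-component scatter figure. The same run is available from Python via
`capnotrace.pipeline.run_pipeline` and, piecewise, through the module
functions (`detect_breaths`, `compute_ventilation`, `qc_cell`,
`classify_population`, `onset_latency`, …).

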