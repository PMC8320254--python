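# Methods

## The analysis in brief

`coldsense` implements a stimulus-locked responder-detection and
population-classification pipeline for in vivo dorsal-root-ganglion (DRG)
calcium imaging of sensory neurons. GCaMP fluorescence is recorded at
1.55 Hz while thermal and mechanical stimuli are applied to the hind paw;
the question is which neurons respond to which stimuli, and whether a
normally cold-insensitive population of large-soma neurons ("silent
cold-sensing neurons") has acquired de novo cold sensitivity, as happens in
neuropathic pain states.

## Responder detection

For each cell and stimulus:

1. The raw ROI-mean trace is smoothed with a **trailing (causal) 4-point
   moving average**. Trailing rather than centred alignment was chosen so no
   post-stimulus sample leaks into the pre-stimulus baseline; the first
   three samples average over the available prefix.
2. The first difference of the smoothed trace, divided by the frame
   interval, gives the derivative (intensity/s). A derivative sample is
   timestamped at the *end* of its frame interval for window assignment.
3. Baseline statistics (mean and sample SD, n−1) are computed on derivative
   samples in `[onset − 10 s, onset)`; the derivative z-score is evaluated
   on samples in `(onset, onset + 30 s]`, truncated at the next stimulus
   onset if that comes sooner. The onset frame itself belongs to neither
   window.
4. A cell is a **responder** iff max z ≥ 5 *and* ΔF/F₀ ≥ 0.25, where
   F₀ is the mean *raw* trace over the baseline window and F_peak the max
   *smoothed* trace in the response window. Using the smoothed peak is
   conservative against single-frame noise spikes. Non-responders carry a
   `below_z` or `below_dff` discard reason; ΔF/F₀ is reported for all pairs.

Degenerate baselines (SD = 0, which arises only on noise-free synthetic
input) switch to a strict-exceedance rule and set a `degenerate_baseline`
flag instead of raising, so zero-noise fixtures stay usable. There is no
manual trace screening; the machine-readable flags (degenerate baseline,
truncated window, registration QC) replace it.

The reported response onset is the *start* of the first supra-threshold
derivative interval: the rise began somewhere inside that interval, and
start-attribution bounds the onset error by one frame, which matters when
converting onsets to thermal thresholds on a Peltier ramp (threshold error
stays within one frame-equivalent °C at the tested ramp rates).

Invariants tested: responder sets shrink monotonically as either gate is
raised; z and ΔF/F₀ are invariant under positive rescaling of a trace;
adding a constant offset preserves z but shrinks ΔF/F₀ (F₀ grows).

## Window conversion

Windows are stated in seconds and converted to frames as
`floor(duration × frame_rate)` with a minimum of 2 — 15 baseline and 46
response frames at the defaults. Floor is our choice; nothing in the
protocol dictates how fractional frames are handled.

## Soma-area classification

Cold responders are split by soma cross-sectional area. A least-squares
Gaussian `a·exp(−(x−µ)²/2σ²)` is fit to the histogram of *control-condition*
cold-responder areas (bin width 80 µm², bins anchored at 0, initialised
from sample moments). The silent/basal cutoff is `µ + 3σ`; cold responders
strictly above it are **silent**, at or below it **basal**, and the class is
defined only for cold responders — a large pinch-only cell is never
"silent". At the published control fit (µ = 214.9, σ = 77.29 µm²) the
cutoff is 446.77 µm²; at the nerve-injury sham fit (222.7, 60.9) it is
405.4 µm².

**Sheppard's correction.** Fitting bin *counts at bin centres* inflates the
fitted width: binning adds ≈ w²/12 to the variance, a systematic +4–5% in σ
at w = 80 µm², σ ≈ 77 µm². The fitted σ is therefore corrected to
`sqrt(σ² − w²/12)` (skipped in the degenerate case σ² ≤ w²/12), making the
estimator unbiased for the generating SD — parameter-recovery tests confirm
bias < 1% for µ and σ at n = 5000. A neuropathic histogram is never fit
with a two-component mixture; like the original analysis, only the control
component is fit and thresholded.

Sessions with fewer than 20 cold responders cannot support a histogram fit;
the pipeline falls back to sample moments (mean, SD with n−1) with a logged
warning so small sessions remain classifiable.

## Marker scoring

tdTomato positivity is a z-score of the cell's mean red intensity against
background: five background ROIs give per-ROI mean intensities, whose mean
and sample SD (across ROI means, not pooled pixels) define the reference;
a cell is positive iff z > 5 strictly. Zero background SD falls back to a
strict mean comparison with a degenerate flag.

## Summaries and statistics

* **Polymodality**: for the pooled cold group and each cold sub-modality,
  the fraction also responding to heat, pinch, brush or von Frey, with
  Wilson 95% CIs. Percentages are rounded half-up, which reproduces the
  published integer percentages exactly (e.g. 45/291 → 15%, 27/81 → 33%).
* **Recruitment curves**: the percentage of cells whose thermal-activation
  threshold drop exceeds x °C, at integer drops — a survival curve in
  percent starting near 100 — with an optional OLS line (slope in %/°C).
* **Statistics**: Wilson score intervals (no continuity correction), Pearson
  χ² on 2×2 tables without Yates correction, the asymptotic two-sample
  Kolmogorov–Smirnov test, OLS with slope standard errors, and a two-sided
  t-test for slope equality (`t = Δb/√(se₁²+se₂²)`, df = n₁+n₂−4). All
  tests two-sided at α = 0.05. Wilson-interval coverage is validated by
  exact binomial enumeration across p ∈ {0.05, 0.2, 0.5}, n ∈ {50, 200},
  rather than by finite simulation, because the exact coverage (93.5–96.7%
  at nominal 95%) sits close enough to the 93% floor that Monte-Carlo noise
  at a few thousand replicates would produce spurious failures.

## Image preprocessing

Registration is **translation-only** cross-correlation to a reference frame
(integer-pixel argmax, optional subpixel upsampling); the original analysis
used rigid-body (translation + rotation) registration, but sub-degree
rotations have negligible effect on ROI means at this magnification.
Rotation support is a listed extension. Axial (Z) movement cannot be
corrected in a single plane, so it is flagged: frames whose Pearson
correlation to the reference falls below `qc_corr_min` (default 0.6) are
listed, and the stack fails QC when more than 10% of frames are flagged.
Both knobs are configuration, not silent policy. ROI masks are label
images supplied by the user; pixel size must also be supplied (the
synthetic default of 1 µm/px is arbitrary).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics:

* **Population**: `n_cells = 500` split into basal-cold (20%), silent
  (24%) and other (56%) classes; areas from class Gaussians truncated at 0
  — N(214.9, 77.29²) for small cells, N(820.1, 200²) for silent cells (the
  large-cell SD is not published; 200 µm² keeps the two modes separated as
  in the published histograms). Silent cells gain a cold response with
  probability `unmask_prob` (0 control; 0.8 neuropathic, which puts the
  true silent fraction among responders near the published 19%).
  Non-cold modality responses and marker positivity follow per-class
  probability tables loosely matched to the published proportions.
* **Traces**: baseline F₀ = 100 AU plus Gaussian noise of SD 2% of F₀;
  each true response is a transient with 1 s linear rise, 3 s plateau and
  5 s exponential decay, peak `ΔF/F₀·F₀` with amplitudes uniform on
  0.3–3.0. The plateau ensures the smoothed-trace peak reports the true
  amplitude despite the 4-point average; real transients have no such
  plateau guarantee, so amplitude recovery on real data will be biased low
  for fast transients. Kinetics are configurable; a `long_decay` flag
  (τ = 30 s) emulates prolonged acetone-type responses and is off by
  default. No photobleaching, neuropil contamination or indicator-binding
  model is included — passing tests show the *pipeline logic* recovers the
  generated truth, not that real recordings behave this way.
* **Stimulus battery**: six stimuli (ice water, acetone, heat 55 °C, pinch,
  brush, 2 g von Frey) spaced 45 s apart, first onset 15 s; spacing below
  30 s is rejected. Peltier ramps carry a linear temperature profile, and a
  cell with a generated activation threshold starts its transient when the
  ramp crosses it.
* **Red channel**: marker-positive cells sit 20 background SDs above the
  background mean, so the z > 5 rule recovers truth with margin; negatives
  scatter ~1 SD.
* **Image stacks**: cells are rendered as non-overlapping discs whose pixel
  count matches their area; the green channel inside a disc equals the
  trace value, so trace extraction is exactly invertible at zero noise and
  drift; integer per-frame drift is applied with wrap-around, making
  planted-shift recovery exact.

All randomness flows from a single seed (per-cell seeds derived from it),
and identical seeds give byte-identical pipeline outputs.

## Problem sizes

Default synthetic sessions use 500 cells × 6 stimuli (~450 frames/trace);
detector-recovery checks use 200 cells; Gaussian parameter recovery uses
5000 areas × 20 seeds. These sizes give binomial/fit noise comfortably
inside the tolerances being checked while keeping a full run under a few
seconds on one core.

## Known limitations

* Translation-only registration (no rotation).
* The Z-movement metric is a correlation surrogate, not a measurement.
* Single-Gaussian area model; bimodal histograms are thresholded, not
  mixture-fit.
* ΔF/F₀ magnitude comparisons across groups (Mann-Whitney etc.) are not
  re-implemented; the exported per-cell tables make them one-liners in any
  statistics environment.
* The published raw-data regressions (e.g. recruitment slope −2.883 %/°C)
  depend on the original recordings and are reproduced only qualitatively
  through generator-truth recovery.
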