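# Methods

This note documents the models, parameter choices and numerical conventions
behind `fusbbb`, and what the synthetic-data generators do and do not
emulate.

## Feedback controller

The controller is a faithful state machine of the published sonication
scheme: bursts at f0 = 1.68 MHz, 1 Hz PRF, 120 s; pressure ramp
0.2 MPa + 0.02 MPa per burst; drop to 25 % of peak on detection. Design
points that were genuinely open:

- **Trigger.** The default `trigger_mode="ultra_only"` drops the pressure on
  ultra-harmonic detection only; sub-harmonic detection is still recorded.
  The alternative `sub_or_ultra` is a config switch. Rationale: the ramp is
  described as running "until ultra-harmonic signals" appear, while both
  tones are monitored.
- **Timing.** The detecting burst itself defines the peak (it ran at the
  peak pressure); the 25 % plateau applies from the next burst.
- **Detector.** The original real-time detector's spectral estimator, band
  width and threshold are not published. Here: band power is the maximum
  magnitude within ±50 kHz of 0.5 f0 / 1.5 f0; the noise floor is the median
  magnitude outside the 0.5/1/1.5/2·f0 bands (median so injected tones
  cannot inflate it); detection requires ≥ 6 dB above floor. All three are
  configurable.
- **Derating.** Traces store source pressure; `derate_pressure` applies
  (1 − 0.18) · exp(−5 Np/m/MHz · 1.68 MHz · 2.5 mm) ≈ 0.803 when in-situ
  values are reported.

The emission model is phenomenological: a flat noise floor with 0.5 dB/bin
lognormal jitter and tones injected 10 dB above the floor once the per-focus
onset pressure is reached. It makes no claim about bubble physics; it exists
so the controller's ramp/drop logic and detector can be exercised
deterministically. The 10 dB tone against the 6 dB threshold with 0.5 dB
jitter makes detection unambiguous by construction.

## Image model and closure classification

Synthetic series are 2D 96×96 axial slices (the published quantification is
a 3×3 in-plane ROI, which a slice suffices to exercise; `roi_mean` also
accepts 3D input and takes the focus's plane). The sonicated hemisphere is
columns 0–47; four focus centers per mouse at (24,16), (24,32), (72,16),
(72,32). Enhancement is an additive Gaussian bump (σ = 2.5 voxels,
amplitude 100) on a background of 100 with additive Gaussian noise
(sd 10, i.e. the 10:1 amplitude:noise default). Closure renders as a step to
background at the first assessment time ≥ the programmed closure time —
the schedule observes only at 6/12/20 h, and no continuous decay model is
claimed.

Classification follows the 2-SD rule against whole-hemisphere contralateral
statistics (sample SD, n−1). The boundary case (ROI exactly 2 SD above the
contralateral mean) is classified permeable — the conservative direction for
a safety readout. A mirrored-ROI comparison (focus ROI vs its mirror across
the midline) could be added, but whole-hemisphere statistics are the
default. Focus localization smooths with a σ = 1.5 voxel Gaussian and picks
strict local maxima greedily with an 8-voxel exclusion radius; a uniform
image has no strict maximum and errors. Under the default noise the located
peak can land one voxel off the true center, which leaves the ROI decision
unchanged by a wide margin (the ROI excess is ≈ 9 noise-SD at opening).

At these defaults the probability that noise flips a single focus-timepoint
decision is negligible (the ROI-mean noise is ~noise_sd/3 against a 2-SD
threshold margin of ~7 such units), which is why the full chain recovers the
programmed fixture counts exactly and the reported percentages are stable
across seeds.

What the generator does **not** emulate: MR signal formation, B1/bias
fields, motion between timepoints, partial-volume effects, mouse-to-mouse
background variation, or continuous contrast washout. Passing tests
demonstrate the pipeline's logic and statistics, not robustness to those
real-data effects.

## Closure fixtures

The study prints percentages, not counts. The canonical fixtures reconstruct
counts such that count/n rounds to the printed percent-permeable values with
n inside the legend's 21–24 range:

| group | n | closed ≤6 h | 6–12 h | 12–20 h | permeable 20 h |
|---|---|---|---|---|---|
| TgCRND8-VT | 23 | 17 | 2 | 1 | 3 |
| TgCRND8-PBS | 21 | 4 | 2 | 5 | 10 |
| nonTg-PBS | 24 | 4 | 7 | 3 | 10 |
| nonTg-VT | 23 | 9 | 8 | 0 | 6 |

The 20/23 = 87.0 % closed fraction for TgCRND8-VT follows the abstract's
figure (the results text rounds the same curve to 86 %).

## Survival analysis

Closure is interval-censored in reality (a focus closed somewhere between
two scans); events are scored at the right endpoint — the assessment time —
matching the per-timepoint readout and the step curves. Foci permeable at
the last scan are right-censored at 20 h. The log-rank statistic is the
standard pooled-hypergeometric Mantel–Cox form with exact tie handling at
the three discrete event times; censored units at 20 h leave the risk set
after the 20 h events. Re-opened foci (a noisy-classifier anomaly) take
their first closure as the event and are logged. No frailty/clustering
correction is applied: focal spots are independent units by design.

## Evans-blue calibration

"Semi-log" is implemented as radiance linear in log10(ng), base 10 being the
conventional plotting base. When no range is given, the linear portion is
the contiguous span of ≥ 4 standards maximizing R² (ties: longest span, then
lowest start). This rule exists to exclude saturated top standards; on a
noisy curve with *no* saturation it can prefer a short high-R² span, so when
the linear portion is known (e.g. synthetic standards without saturation)
pass `linear_range` explicitly. Radiances beyond the calibrated span warn
and extrapolate rather than error — a heavily opened brain can exceed the
top standard. Regions below the lowest calibrated radiance report 0 ng,
flagged below-detection.

## Group statistics

- ANOVA: Type-III sums of squares via effect-coded (+1/−1) drop-term
  contrasts on the 2×2 design with interaction, the convention of the
  commercial software used in the study, valid for the unbalanced n = 21–24
  cells. A numerically degenerate dataset (zero residual and effect SS at
  ~1e−12 relative tolerance) reports F = 0, p = 1.
- Tukey–Kramer: all six pairwise cell comparisons, studentized-range
  distribution with k = 4 and pooled within-cell MSE; the Kramer SE handles
  unequal cell sizes.
- Grubbs: two-sided (max |x − mean|/s), critical value
  ((n−1)/√n)·√(t²/(n−2+t²)) with t the upper α/(2n) t-quantile at n−2 df;
  a zero-SD sample reports no outlier.

Independent oracles in the test suite: lifelines (log-rank), statsmodels
(Type-III ANOVA, Tukey HSD), plus brute-force hypergeometric sums and
closed forms. The implementations never call those libraries.

## Problem sizes and determinism

Default study conditions throughout: 21–24 foci per group, 96×96 slices at
four timepoints, n = 24 per cell for the threshold statistics, 25 %
effect-size reduction for the treated transgenic group (within the reported
21–29 %). Calibration checks use 1000 replicates (log-rank and ANOVA
type-I error), 200 seeds (Tukey power), 100 seeds (noise-robustness and
Evans-blue recovery). Every generator and the pipeline drivers take an
explicit integer seed and are bit-reproducible under it.
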