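# Methods

This package implements a context-aware stress-detection analysis for
wrist-wearable data: activity and sleep context are derived from the raw
signals (a supervised activity recognizer and an unsupervised rest-period
detector), hourly physiological features are extracted, and a four-model
ablation quantifies how much activity and sleep context add to a
physiology-only stress classifier. Real cohort data of this kind is not
redistributable, so a synthetic-data generator with known ground truth
stands in for the cohort; it is first-class, tested code, and its design
determines exactly what the experiments can and cannot show.

## Data model

A recording holds five uniformly sampled channels per subject: three
accelerometer axes at 32 Hz (units of g) and galvanic skin response
(GSR, µS) and skin temperature (°C) at 4 Hz. All intervals are half-open
`[start, end)`; a timestamp labels the left edge of its interval. Hours
with less than 80 % of expected samples in any channel are flagged
unusable and excluded from feature extraction; this completeness rule is a
convention of this package (mirroring the quality-index convention used
for wearable data), not a property of any particular device.

## Feature extraction

Two fixed catalogues define the feature-table contracts:

* **Hourly physiology** — 73 named statistics (time- and frequency-domain)
  applied to each of the five raw signals: 365 values per hour. No
  band-pass preprocessing is applied on this path.
* **HAR windows** — 15 s windows with 50 % overlap (7.5 s stride). The
  accelerometer axes and their Euclidean norm (norm computed before
  filtering) are band-passed (Butterworth order 4, 0.3–15 Hz) and receive
  time- plus frequency-domain features; the z-normalized GSR is split into
  tonic (4 s centered moving average) and phasic (residual) components and
  these, plus raw skin temperature, receive time-domain features only:
  exactly 228 values per window.

The catalogues are CSV data files; the cardinalities (73 / 228) are
asserted at load time because downstream file layouts depend on them. The
specific feature identities are this package's own documented choices from
the standard automated time-series feature vocabulary; users can
substitute their own catalogue files as long as the cardinalities hold.
The tonic/phasic split is a moving-average surrogate with phasic defined
as the residual, which makes tonic + phasic = z-normalized signal an exact
identity. Frequency features use a single full-window periodogram with the
DC bin removed; degenerate inputs (constant series, zero spectra) map to 0
rather than NaN. NaN stretches inside usable windows are linearly
interpolated before feature computation.

## Activity recognition (HAR)

A LightGBM gradient-boosted-tree classifier over the 228 window features
predicts sedentary / walking / cycling. Tree depth is tuned over
{4, 6, 8, 10} by subject-grouped 5-fold cross-validation (macro F1), class
weights are `n_total / (n_classes · n_class)`, and the final model is
refit on all training subjects. Windows must lie entirely inside a
ground-truth bout to be labelled, and bouts shorter than one minute are
discarded. At inference, window probabilities at the 7.5 s stride are
summed per clock minute (a window belongs to the minute containing its
start); the argmax is the minute label, ties resolved in class order
(sedentary first). Minute labels are counted per hour into the three
activity-minute context features; unlabeled minutes simply do not count.

## Sleep detection

Unsupervised, from accelerometry alone, per 13:00 → 13:00 day window:

1. **Activity index**: per minute, `sqrt(mean per-axis variance)` over the
   trailing 10 min window. Axes are mean-centered before the cumulative
   sums to avoid cancellation; the index is invariant to that shift.
2. **Smooth and scale**: third-order zero-phase Butterworth low-pass on
   the minute series (cutoff 0.04 cycles/epoch ≈ 25 min; on a minute-scale
   nonnegative series a high-pass edge would destroy the level information
   the segmentation needs, so the band-pass degenerates to low-pass), then
   min–max scaling to [0, 1] within the day window (a constant series
   scales to zeros). Min–max scaling makes the result invariant to overall
   accelerometer gain.
3. **Cole-style scores**: a weighted moving sum over epochs t−4 … t+2 with
   the canonical minute-scale weight profile (404, 598, 326, 441, 1408,
   508, 350 × 1e−5) and a calibration gain (default 200); score < 1 is
   scored asleep. The gain is a configuration knob: the weight profile was
   designed for wrist count data, and the scaled activity index needs a
   gain for typical wake activity to score above threshold.
4. **Segmentation**: the exact least-squares two-change-point split of
   `log(score + 0.05)` with the two change points at least 5 h (300
   epochs) apart. The log compresses daytime exercise spikes so the
   change points respond to the wake/sleep level shift rather than to the
   largest bursts; the additive offset keeps the log finite at zero
   activity. The search enumerates all admissible pairs with prefix sums
   (≤ 1440 epochs per day window), so it is exact rather than greedy.
   The enclosed segment is accepted as the rest period only when its mean
   scaled activity is below both flanks and at least half of its epochs
   are scored asleep; otherwise the window yields `no_sleep_detected`.

The detected onset carries a small positive bias (≈ 5–10 min) because the
activity-index window is trailing; the offset bias is smaller, so duration
is nearly unbiased. Scores are diagnostic and gate the segmentation; the
change points are authoritative for onset/offset.

## Stress experiment

Hourly stress reports on a 5-level scale collapse to three classes
(1 → no, 2 → medium, 3–5 → high). Each reported hour with usable
physiology becomes an event holding the 365 physiological features plus
six context features: activity minutes (sedentary, walking, cycling) and
sleep (bed hour-of-day, get-up hour-of-day, duration in hours; hours are
plain reals, duration is the circular difference). Self-reported activity
context splits the hour's 60 minutes equally over the distinct reported
classes; self-reported sleep context takes the reported times literally.
Machine-learned context uses the HAR hourly activity minutes and the
detected rest period of the preceding 13:00 → 13:00 window, in the same
encoding, so variants differ only in context source. Events lacking any
required context are dropped before modelling so all four variants train
on identical rows.

Four LightGBM models (physiology only, +activity, +sleep, +both) are
trained on subject-grouped 3-fold rotations: rotation r tests on fold r,
validates on fold r+1, trains on fold r+2; the same assignment serves all
variants. Tree depth is tuned over {4, 6, 8} and early stopping (patience
150, at most 10 000 iterations) maximizes quadratic-weighted kappa on the
validation fold — quadratic weighting respects the ordinal class order —
while the reported kappa is the unweighted Cohen statistic. Metrics per
rotation: accuracy, Cohen kappa ×100, weighted F1, and weighted F1 minus a
majority-class dummy (majority taken from the training fold), all as
percentages; tables report mean (sd) over the three rotations. The sd
over cyclic rotations of a single grouped 3-fold split is the only
interpretation that yields a dispersion from one split; repeated refits
with different seeds would measure algorithmic noise instead.

## Synthetic cohort generator

The generator renders full days (00:00–24:00) per subject with a
schedule layer (sleep times, activity bouts, stress episodes) and a signal
layer. Signal models are simple parametric processes — Gaussian noise,
band-limited Gaussian noise, Poisson-like phasic events — chosen for
controllability and speed, not physiological fidelity.

Key design features, and why they exist:

* **Stress/exercise confound.** Phasic GSR responses occur at a baseline
  rate (1/min awake, 0.2/min asleep) and the rate rises both under stress
  episodes (+3 to +9/min by level, with per-episode intensity jitter
  0.6–1.4) and during exercise (+4.5/min walking, +6.5/min cycling). Skin
  temperature rises under sleep, exercise and stress by similar amounts.
  Arousal is therefore readable from the physiology, but its attribution
  (stress vs exercise) is not.
* **Motion as band-limited Gaussian noise.** Walking adds a sustained
  narrowband component (1.9 ± 0.35 Hz); cycling adds broadband vibration
  with a weak cadence band. Band-limited noise has a Gaussian amplitude
  marginal — a pure sinusoid's bimodal marginal would be visible to
  hour-level distribution statistics and would identify exercise trivially.
* **Chores.** Sedentary hours contain intermittent "chore" motion
  (typing/stirring-like narrowband plus broadband bursts at ~50 % duty
  cycle), and a fraction of chores are sustained exercise look-alikes with
  the same band, variance and duration texture as a walking or cycling
  bout but without the arousal response. Chore probability rises in
  stressed hours (restlessness). Consequently hour-level accelerometer
  statistics cannot attribute "motion + arousal" hours, while 15 s windows
  remain separable through sustainedness, intermittency and the
  physiological channels — which is precisely why the HAR feature set
  includes GSR and skin temperature.
* **Inter-individual variability.** Per-subject lognormal gains on
  accelerometer amplitude (σ = 0.35), phasic amplitude (σ = 0.4) and
  phasic event rate (σ = 0.5) prevent amplitude thresholds learned on one
  subject pool from transferring to unseen subjects under grouped
  cross-validation.
* **Sleep–stress link.** Stress-episode probability rises with the
  previous night's sleep debt (0.30 baseline + 0.28 per hour of debt
  below a 7.5 h reference, clipped to [0.05, 0.80]) and episode intensity
  tilts higher under debt. In addition, reported levels in non-exercise
  hours are amplified under debt (probability 0.6 per hour of debt, capped
  at 0.9, of reporting one level higher; the converse after long nights)
  — an appraisal effect that is invisible to the wearable, so sleep
  context carries label-relevant information physiology cannot.
* **Self-report noise.** Activity tokens are omitted with probability
  0.1, whole hourly reports are missing with probability 0.15, reported
  levels are off by one with probability 0.2, and reported bed/get-up
  times carry 35 min Gaussian error (comparable to the discrepancies
  reported for such annotations). Stress episodes have variable duration
  (20–90 min) so their temporal footprint resembles exercise bouts and
  cannot be told apart by hour-coverage alone.

What passing the experiments shows, and what it does not: the ablation
demonstrates that when arousal attribution is ambiguous and part of the
label is appraisal-driven, context features improve held-out-subject
stress classification — the mechanism the analysis is designed to expose.
It does not demonstrate effect sizes on real cohort data; real wearable
data differs in motion diversity, sensor artifacts, physiological dynamics
and reporting behaviour, and absolute numbers here are properties of the
generator's settings.

## Problem sizes

The test suite and the bundled analyses use scaled cohorts chosen as this
package's own study sizes: the directional ablation runs 12 subjects × 4
days × 3 cohort seeds (~450 events per seed) with self-reported context and
asserts the pooled ordering of mean accuracy; the machine-learned-context
pipeline is exercised end-to-end on 6 subjects × 2 days; sleep recovery
uses 50 planted nights; HAR recovery uses 10 training / 3 held-out
subjects. The generator's signal and noise parameters are identical at
every size; only the number of subject-days varies.

## Numerical and degenerate-input conventions

* Butterworth filtering is zero-phase (forward–backward) everywhere so
  features and change points are not phase-shifted against labels.
* The HAR band-pass high cutoff (15 Hz) must stay below Nyquist; the
  filter rejects violations rather than silently capping, and the 4 Hz
  channels never pass through the accelerometer filter.
* Z-normalization of a constant series yields zeros (zero-sd convention).
* Min–max scaling of a constant series yields zeros.
* Tied minute-label probability sums resolve to the earlier class in
  (sedentary, walking, cycling).
* All randomness flows from `numpy` `SeedSequence` spawning per subject
  and stream; every entry point is byte-reproducible given its seed, and
  model fits run single-threaded with fixed seeds.

## Known limitations

* The synthetic generator's activity repertoire (4 states + 2 chore
  archetypes) is far narrower than real life; hour-level activity leakage
  into physiological features is controlled by construction, not learned
  from data.
* The sleep detector finds exactly one rest period per day window: no
  naps, no awakenings, no sleep quality.
* The rest-period onset inherits a small positive bias from the trailing
  activity-index window; applications needing unbiased onsets should
  subtract half the window length.
* Hour-of-day context features are plain reals; a circular encoding is
  available behind a configuration flag but off by default, matching the
  "start hour of sleep" featurization the experiment specifies.
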