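# Methods

## Problem and data model

A chest-worn light logger reports, once per minute: photopic illuminance
(lux), melanopic equivalent daylight illuminance (mEDI, lux), an
accelerometer time-above-threshold (TAT) count, and an orientation code
(2 = hanging upright as a pendant, 16 = face up, 32 = face down; other codes
are treated as "other"). The photometric operating range is 1–100,000 lux.
Timestamps are stored timezone-naive in local clock time; streams must be
strictly increasing at whole-minute spacing within a segment, and larger
gaps are flagged rather than filled. DST transitions are out of scope.

Ground truth comes from a light diary of half-open intervals `[start, end)`
tagged with one of nine wear conditions (four wear variants, two night
placements, three non-wear variants). These collapse onto three modelling
outcomes: all `WEAR_*` conditions → WEAR; `NIGHT_FACE_UP` → NIGHT_OK
(appropriate overnight bedside placement, sensor unobscured);
`NIGHT_FACE_DOWN` and all `NONWEAR_*` → NONWEAR — a face-down device cannot
measure light, so it counts as non-adherent even at night. Minutes outside
every diary interval are UNKNOWN and are kept in the stream but excluded
from training and evaluation.

## Predictors

Five per-minute predictors: `movement = TAT > 0`, `upright = (orientation ==
2)`, `face_down = (orientation == 32)`, `dark = (photopic ≤ 1 lux)`, and
time of day as raw minutes since midnight (linear). Face-up orientation is
deliberately not a predictor: any non-face-down pose can see light, so
face-up carries no extra information beyond "not face down and not upright".
Time of day enters linearly by default; a cyclic sine/cosine encoding is
available (`FitConfig(tod_encoding="cyclic")`) but off by default. The
linear encoding cannot wrap across midnight, which is acceptable because the
night window (00:00–06:00) sits at one end of the scale; the cyclic option
exists for schedules that straddle midnight.

Binary features can be re-binned to hour-aligned 5/10/20/30-minute epochs by
majority vote for epoch-length comparisons. The aggregation rule is a design
choice: ties resolve to 1 (presence of signal) for all four binaries, and
the epoch's time of day is its midpoint. The pipeline default remains the
native 1-minute epoch.

## Classifier

Three one-vs-rest binary logistic regressions (WEAR, NONWEAR, NIGHT_OK over
intercept + the five predictors), rather than one multinomial fit, because
model quality is reported per class (AUC, sensitivity, specificity), which
presupposes per-class scores. Fitting is iteratively reweighted least
squares (Newton with step halving) run to a score sup-norm below 1e-8 or
100 iterations.

Complete or quasi-separation is expected on cleanly simulated data (e.g. the
upright orientation identifies wear exactly). It is detected when the
unpenalized fit fails to converge or its linear predictor exceeds ±30
(probabilities numerically 0/1); the class is then refitted with a ridge
penalty of 1e-6 on slopes (never the intercept), flagged in the model
metadata, and a warning is emitted. The penalized optimum still has very
large coefficients, so downstream ranking and thresholding work on the
linear predictor (log-odds) scale: `expit()` of a log-odds value beyond
roughly ±37 rounds to exactly 0/1 in double precision, which would collapse
distinct scores into ties and erase the fitted decision boundary. The
public `predict_proba` still returns probabilities; `decision_scores`
returns the log-odds.

Per-class decision thresholds are the Youden-optimal points (max J =
sensitivity + specificity − 1) of the training ROC, selected on the
log-odds scale and stored both as a probability (clipped into (0,1)) and as
the exact log-odds cut. A minute's label is the argmax over classes of the
threshold-shifted score, computed as `expit(eta − eta_threshold) − 0.5`
(same sign and per-class ordering as probability minus threshold); exact
ties break by the fixed priority NIGHT_OK > WEAR > NONWEAR, preferring the
rarer, time-gated class. The priority is configurable in source and
documented here because the argmax is genuinely degenerate only when
several saturated classes pass their thresholds simultaneously.

Train/validation splitting is by whole calendar days (day blocks), not
per-minute sampling, to avoid temporal leakage between adjacent minutes; the
train share is the requested fraction rounded to whole days, and the
partition is deterministic under a fixed seed.

## Evaluation

ROC curves are built over all distinct score values (predict positive when
score ≥ threshold) plus a +inf sentinel. AUC accumulates the trapezoidal
rule on the integer (FP, TP) lattice and divides once by `2·n_pos·n_neg`,
making it exactly the Mann–Whitney pair count with half credit for ties.
Youden selection compares the integer numerator `tp·n_neg − fp·n_pos`, so
ties are exact and break toward the higher (more specific) threshold; the
sentinel (classify-everything-negative) is never returned. AUC bands: < 0.8
poor, [0.8, 0.9) good, ≥ 0.9 excellent discrimination.

Confidence intervals use a seeded percentile bootstrap (default 1,000
resamples, 95 % level). Percentile rather than BCa is a deliberate
simplicity choice; its small-sample coverage for a mean at n = 200 is
verified empirically in the test suite (95 % ± 3 % over 500 outer
replications).

## Adherence

A participant-day is adherent when at least 80 % of the recorded minutes in
the 10:00–20:00 window are classified WEAR; a night when at least 80 % of
00:00–06:00 minutes are NIGHT_OK (the night target class is configurable —
whether appropriate night use should also credit WEAR minutes is left to
the caller, default NIGHT_OK only). The windows are fixed clock intervals
precisely so weekdays and weekends are scored identically. Minutes missing
from the recording are excluded from the denominator (a device gap is not
evidence of non-adherence) and reported, so callers can apply a stricter
policy; a window with zero recorded minutes is flagged undefined rather
than scored 0. Participant inclusion defaults to ≥ 1 adherent day; a
stricter preset (≥ 6 usable days, ≥ 3 nights — `USABLE_WEEK_PRESET`)
mirrors an observed usable-week pattern without mandating it.

## Exposure metrics

* **Luminous exposure**: sum over minutes of photopic lux × (1/60 h) / 1000,
  in kilolux·hours per 24 h; missing minutes contribute 0 and are reported
  via a warning.
* **Bright minutes**: count of minutes strictly above 1,000 lux photopic.
* **Recommendation compliance**: percent of recorded window minutes with
  mEDI ≥ 250 lux (07:00–17:00), ≤ 10 lux (20:00–23:00), and ≤ 1 lux
  (00:00–06:00); boundaries follow the wording "minimum", "maximum", "1 lux
  or less".
* **24-h profile**: per minute-of-day mean of log10(lux + 1) across days;
  the +1 lux offset handles zeros and sits at the device floor. CIs
  bootstrap whole days.
* **Profile shift**: the integer circular shift in ±200 minutes that
  maximizes Pearson correlation between a profile and a reference. Shifting
  wraps across midnight because 24-h profiles are periodic. The returned
  value is the shift *applied to the profile* at the maximum, so
  `profile_shift(roll(p, s), p) == -s` and a profile delayed relative to
  the reference yields a negative value; ties break toward the smallest
  |shift|, then the negative one. Profiles are not smoothed by default
  (`smooth_profile` is available as an opt-in circular moving average).
  Constant profiles raise an error (correlation undefined).

## Indoor/outdoor cut-points

Labelled environment observations must span at least 5 minutes and are
summarized by the offset geometric mean `exp(mean(log(x + 1))) − 1` for both
channels — geometric because illuminance is multiplicative, offset because
indoor observations genuinely contain 0 lux minutes. The cut-point is the
Youden-optimal threshold of an ROC with OUTDOOR as the positive class,
evaluated on midpoints between adjacent sorted observation values (so the
returned threshold falls strictly inside a gap, and scaling all
observations by c scales the threshold by c). Above-ground transport
observations read like outdoor light while being neither; they are excluded
from fitting automatically but can be summarized for reference. No
automatic outlier exclusion is performed — an implausible observation is
the caller's call. A minute or observation above the threshold (strict >)
reads as OUTDOOR.

## Simulator

The simulator provides the labelled ground truth that no public dataset
offers. A daily episode schedule (the tester template covers all nine
conditions; a free-living participant template is mostly-adherent wear with
short off-body episodes) assigns each minute a condition; each condition
imposes a sensor signature (orientation, movement probability, illuminance
regime) as tabulated in `luxwear/simulate.py`. Choices and defaults:

* **Illuminance** is hierarchical lognormal: an episode-level value
  (between-episode log-SD 1.0, natural log) redrawn every 30 simulated
  minutes, times minute noise (within log-SD 0.3), clipped to
  [0, 100,000] lux. Geometric means default to 202 lux indoor and
  10,241 lux outdoor; the log-SDs were chosen so that 45 indoor / 21
  outdoor simulated observations span ranges of roughly 0–1,700 and
  500–45,000 lux respectively. Night face-up ambience is dim lognormal
  (gm 0.3 lux); all dark conditions draw uniform 0–1 lux.
* **mEDI** is a per-environment multiplicative fraction of photopic (0.8
  indoor, 0.9 outdoor) with 5 % lognormal jitter — a simulator convention,
  since no joint photopic/mEDI model is specified anywhere.
* **Movement**: per-minute Bernoulli with rates 0.9 (active), 0.5 (generic
  wear), 0.6 (outdoor), 0.15 (sedentary); TAT magnitudes are 1 + Poisson(2)
  when moving, because only the binary TAT > 0 enters the model and real
  count magnitudes are device-internal.
* **Nights**: the 00:00–06:00 slot is face-up by default and flipped to
  face-down on configured day indices (testers: days 1 and 4 of the week,
  so both night conditions appear on both sides of any 80/20 day split;
  participants: days 2 and 5, i.e. five adherent nights in seven).
* **Overlap dial**: with probability `overlap`, a minute's signature is
  replaced by one drawn from a different condition. This is the single
  knob used to study how classifier performance degrades as condition
  signatures blur; the default is 0.
* One `numpy` generator seeded once per call drives all draws, so streams
  are bit-reproducible.

What the simulator does **not** emulate — and hence what passing tests do
not show about real recordings: solar geometry and weather (no
sunrise/sunset structure in outdoor lux), gradual transitions between
environments, diary timing errors and device clock drift, partially
obscured sensors (clothing), or orientation chatter. Real data will be far
less separable than the default simulation; the overlap dial is a coarse
stand-in for all of these at once.

## Problem sizes used in checks

The end-to-end checks simulate four testers of 4–7 days (5,760–10,080
minutes each), train on 80 % of tester 1's days and validate on the rest;
the cohort application uses 20 participants × 7 days; cut-point recovery
uses 200 replicates of 45 indoor / 21 outdoor observations; bootstrap
coverage uses 500 outer replications at n = 200. These sizes make the whole
suite run in well under a minute while keeping the Monte-Carlo tolerances
meaningful.

## Known limitations

* The linear time-of-day term cannot represent activity patterns that wrap
  midnight; use the cyclic encoding for shift workers.
* One-vs-rest scores need not sum to 1 and the argmax rule can in principle
  assign a class whose score is below threshold when all are.
* Under complete separation the reported coefficients are ridge-regularized
  boundary solutions, not finite MLEs; their magnitudes are not
  interpretable (the decision boundary and rankings are).
* The adherence windows, recommendation bands and 80 % rule are fixed
  defaults of the implementation, configurable but not auto-tuned.
* Diary/device clock reconciliation is not implemented; diary intervals are
  taken at face value.
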