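# Methods

## Problem and signal model

A triaxial accelerometer is attached to a drinking bottle with its *x*
axis along the bottle's vertical axis, *y* tangential and *z* normal to
the surface. When dynamic acceleration is negligible the sensor reads the
gravity direction in the bottle frame, from which two angles are
recovered per sample:

- **inclination** θ = atan2(√(a_y² + a_z²), a_x) ∈ [0°, 180°] — how far
  the bottle is tipped from vertical;
- **axial angle** α = atan2(a_z, a_y) ∈ (−180°, 180°] — the sensor's
  angular position in the bottle's cross-sectional plane.

θ carries the drinking kinematics (you must tip an emptier bottle
further); α is the segmentation handle: the lid forces drinking from one
edge, so axial rotations occur while carrying the bottle but are
suppressed while actually sipping.

Both arctangents are evaluated four-quadrant. When the bottle is upright
(a_y = a_z ≈ 0) α is undefined; the estimate carries the last defined
value forward (0° before any). θ does the same in the doubly degenerate
case (free fall / dropout).

## Conditioning

Per trial: (1) per-axis bias from the mean of the first 50 samples, with
the *x* offset taken relative to +1 g so gravity stays in the corrected
signal; (2) samples inside proctor-flagged exclusion intervals dropped,
the uniform grid interpolated across the gap; (3) linear-interpolation
resampling onto a uniform 20 Hz grid (the radio polling interval of such
sensors jitters); (4) a causal two-sample moving average,
y[n] = (x[n] + x[n−1])/2 with y[0] = x[0]. Angles are computed after
smoothing. Resampling is idempotent at the target rate, and linear
interpolation is exact on affine signals — both are tested.

## Segmentation

**Macro-events** (one per drink) are found from a per-sample motion
indicator: |‖a‖ − 1 g| > 0.05 g, or the rolling standard deviation of θ
over 0.5 s above 2°, or θ itself above 5°. The third term encodes that
the bottle rests *upright* between drinks — a bottle held steadily at
drinking angle is in-event even though nothing varies. Indicator runs
separated by less than 1 s of stillness are joined; joined runs shorter
than 1 s are discarded. All thresholds sit in `SegmentationConfig`.

**Micro-events.** Within a macro-event, a sample is compliant when the
sample-over-sample |Δα| ≤ 8°/sample (first sample compliant by
convention; differences wrapped to (−180°, 180°] so the ±180° branch cut
cannot fake a jump). Maximal compliant runs separated by fewer than 2
non-compliant samples are merged, gap samples included; the longest
merged run is the **sip** (ties → earliest), with **lift** before and
**place** after. The three ranges tile the event exactly. A property
test checks the result against an exhaustive enumeration of every
admissible merged interval on random series.

## Features

The inclination-signature (IS) vector has 33 entries in a fixed,
versioned registry order:

- 13 kinematic scalars: the four durations (event, lift, sip, place);
  max θ; time-to-max as a fraction of the window; θ at sip start/end;
  mean θ over the sip; max and min forward-difference dθ/dt; trapezoidal
  integrals of θ over the sip and over the event;
- 10 occupancy fractions of θ in equal-width exclusive bins over
  [0°, 180°];
- 10 occupancy fractions of θ/θ_max over [0, 1] (all mass in the first
  bin, with a warning, when θ ≡ 0).

Exclusive binning partitions the amplitude axis, so each group of
fractions sums to 1. `scope="sip"` recomputes the amplitude-shape
features (max, rates, bins) on the sip window only, for models trained on
the stationary drinking phase. Benchmark features for the single-factor
linear models are sip duration, the trapezoidal integral of θ over the
sip, and max θ. Integrals use the trapezoidal rule at the uniform 20 Hz
step throughout.

## Estimation and validation

Volume (grams of water, read as mL) and pre-drink fill ratio are
regressed with epsilon-insensitive SVR on z-scored features. Gaussian
kernels use k(u,v) = exp(−‖u−v‖²/s²) with s = 5.7 ("medium", ≈ √33 for
the 33-dimensional standardised space) or s = 23 ("coarse", ≈ 4√33);
a linear kernel is the third variant. Unless overridden, the box
constraint is iqr(y)/1.349 and the epsilon tube iqr(y)/13.49 (iqr/1.349
being a robust σ estimate). Zero-variance features are dropped with a
warning — on simulated cohorts the highest inclination bins are never
occupied, which is expected.

Validation is leave-one-trial-out: one fold per trial, standardisation
parameters fit on the training folds only and retained per fold so
leakage is structurally auditable. A leave-one-subject-out mode exists
via `group_by` but is not the default, keeping train/test sizes constant
across folds. Two multi-target strategies inject fill-ratio information
into volume models: restricting each test drink's training set to the
k = 150 drinks with the nearest fill-ratio labels (refit per drink), or
appending the fill ratio as a 34th feature standardised with the rest;
either can consume ground-truth or upstream-estimated fill ratios, and
the source is recorded in provenance.

## Metrics

Per-drink error is MAPE (0–100 scale). Aggregate error over the first n
drinks of a trial is OAPE(n) = 100·|Σpred − Σtruth|/Σtruth, averaged
across trials as MOAPE(n); because it compares sums, opposite-signed
per-drink errors cancel. Aggregate consumption can instead be estimated
from endpoint fill ratios, V̂ = β·(FR_i − FR_{f+1}), with β the
container's mL-per-unit-fill-ratio density (equal to capacity for a
uniform bottle). A lone endpoint error |ΔFR| maps to a consumption error
of |ΔFR|/(1 − FR_{f+1}) — the less a trial drank, the more the
conversion amplifies fill-ratio error; `oape_distortion` implements this
closed form and `compare_aggregation` reproduces it to 1e−12 on
constructed single-error trials. With a 12-drink protocol the residual
comparison runs at n = 11, the longest span whose endpoint is itself a
pre-drink estimate. Because pooling per-drink errors and averaging
per-trial means weight unequal trials differently, reports carry both.

## Synthetic cohort

The generator emulates the scripted protocol the pipeline assumes: 12
drinks per trial from a 750 mL bottle refilled at trial start, upright
rests between drinks, small/medium/large volume prompts. Default laws
and levels (all configurable in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| volume mixture | N(20,5²)/N(45,10²)/N(90,25²) g, weights .40/.35/.25, floor 5 g | right-skewed drink volumes |
| tilt law | θ_max = (30° + 60°·(1 − FR_post))·subject tilt | emptier bottle → steeper tilt |
| duration law | (1 s + 0.05 s/mL·v)·(1 + 1.2·(1 − FR_pre))·subject pace | bigger drinks and emptier bottles → longer sips |
| transport | 0.8 s lift / 0.7 s place, ±170° axial rotation, 3 s rests | rotation only outside the sip |
| noise | 0.02 g accel white noise; 2° tilt jitter; lognormal(0.25) duration jitter; lognormal(0.15) transport jitter | sensor + behavioural variability |
| subject effects | lognormal multipliers, σ = 0.10 (tilt), 0.20 (pace), 0.25 (noise) | inter-individual biomechanics |

θ and α trajectories are raised-cosine ramps (continuous derivatives, so
rate features are not boundary artifacts), and the accelerometer is
reconstructed gravity-only — deliberately matching the estimator's
assumption. Each trial draws from its own named stream
(seed, subject, trial), so any trial is reproducible independently of
cohort size or generation order. `SimConfig.noiseless()` zeroes every
stochastic term, under which the pipeline recovers the laws exactly:
12 macro-events per trial, θ_max within 0.5° of the tilt law, and
β·(FR_start − FR_final) equal to the summed drink masses to 1e−9.

The duration law's fill coupling is what ties duration to fill level:
restricting the cohort to narrower high-fill tiers removes that confound
and monotonically strengthens the duration–volume and integral–volume
correlations, while sip duration stays far better correlated with volume
than the transport durations are.

What the simulator does **not** model: dynamic acceleration during
transport (a config flag exists for future use but the default trace is
gravity-only), straw/mug geometries, swallowing micro-structure within a
sip, drift or temperature bias in the sensor, and any realistic
inter-subject covariance beyond independent multiplicative effects.
Passing tests therefore demonstrate pipeline correctness and the
qualitative orderings under the stated laws — not field accuracy on
human data.

## Numerical choices and degenerate inputs

- atan2 everywhere; angle carry-forward thresholds at 1e−6 g.
- Ties for the longest sip run break to the earliest; single-sample gaps
  (gap < 2) merge into the sip and count toward its length.
- Exclusive bin edges are half-open with the final bin closed, so the
  fractions always partition unity.
- iqr(y) = 0 (near-constant response) falls back to C = 1, ε = 0.1.
- Nearest-fill-ratio ties break by original row order (stable argsort).
- MOAPE(n) skips trials shorter than n with a warning rather than
  failing a run; `compare_aggregation` requires drink n+1 and excludes
  (with a warning) trials lacking it.
- Problem sizes: the default evaluation cohort is 40 subjects × 1 trial
  (480 drinks), large enough for stable LOTO orderings while a full test
  run stays in seconds; the cohort generator scales to the 84-subject /
  ~1900-drink design by changing two fields.

## Known limitations

- The macro-event detector is threshold-based and tuned to scripted
  rest-drink-rest structure; free-living traces with confounding
  handling would need the upstream drink-spotting stage this package
  scopes out.
- Fill-ratio labels are per-drink initial levels; the residual-volume
  path cannot span a trial's final drink without a post-trial reading.
- Volume and mass are used interchangeably at water density; other
  liquids require a density correction the label format does not carry.
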