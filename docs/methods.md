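# Methods

## Scope and data model

The package analyzes multimodal free-living wearable data on a 15-minute
grid (half-open intervals `[t, t+15min)`, timestamps UTC, 0-based sample
indexing): interstitial glucose (mmol/L), a food diary (grams of
carbohydrate/fat/protein per logged item), activity samples (energy
expenditure in kcal per sample, acceleration counts, heart rate in bpm) and
nightly sleep records (end time, duration, deep-sleep duration in hours).
Glucose is used in mmol/L throughout.

## Synthetic cohort generator

No participant-level data ship with the package; the generator produces
cohorts whose downstream behaviour is known by construction, so the
detection and prediction stages can be validated against ground truth.

Each subject *i* draws a baseline `b_i ~ N(5.0, 0.3)` mmol/L (floored at 3),
a carbohydrate sensitivity `s_i ~ N(1.0, 0.15)` truncated at 0, a kernel
time constant `tau_i ~ N(45, 5)` min (floored at 15), and mild ±20% jitter
on the activity and sleep coefficients. The glucose trace is composed as

```
g_i(t) = b_i
       + gamma_i * (7 - sleep_hours_previous_night)
       + sum_meals  A_m * u * exp(1 - u),   u = (t - t_m)/tau_i,  t >= t_m
       - beta_i * EE_previous_hour(t)
       + AR(1) noise,
```

with meal amplitude `A_m = s_i * carb_kcal_m / 100` mmol/L (the response
peaks at `t_m + tau_i` with value `A_m`), `beta = 0.002` mmol/L per kcal,
`gamma = 0.05` mmol/L per hour of sleep below the neutral 7 h, and AR(1)
noise with stationary SD 0.15 mmol/L and lag-1 correlation 0.5 (innovation
SD `0.15*sqrt(1-0.5^2)`). Traces are floored at 0.1 mmol/L. Defaults keep
traces in the normoglycemic ~4–8 mmol/L range; all parameters are
config-exposed (`CohortConfig`).

Meals: 3–5 per day — mains jittered N(0, 30 min) around 07:30/12:30/18:30,
snacks at 10:30/15:30 — with uniform macro grams (carb 20–100 g, fat and
protein 5–40 g). A third of meals are logged as two diary items 3–12 min
apart, exercising the meal-chaining rule in-pipeline. Activity is sampled
every 5 min (resting EE ≈ 6.5 kcal/5 min) with 0–2 daily bouts of 30–60 min
that raise EE, acceleration (≈3000 counts) and heart rate
(`hr = 60 + 0.02*acn + noise`), giving ee/acn/ahr the correlation structure
the grouped-importance analysis assumes. Sleep ends around 07:00 with
duration N(7.2, 0.8) h clipped to 4–10 h; deep sleep is 15–25% of duration.
Device failures are injected per modality as contiguous daily gaps (default:
glucose 4%/day, activity 6%/day, 2–8 h; whole sleep records 3%/day), because
data loss in such studies comes from whole-device episodes.

What the generator does **not** emulate: physiological insulin–glucose
dynamics (no ODE model), sensor warm-up artifacts, circadian baseline
drift, meal-composition effects beyond carbohydrate load, stress or
menstrual covariates, or diary misreporting. Passing tests therefore
demonstrate that the pipeline recovers the signal structure it is pointed
at — not that real cohorts carry that structure.

## Preprocessing rules

* **Meal aggregation**: diary items are chained transitively while
  consecutive items are ≤ 15 min apart; the event carries the first item's
  timestamp. Calories use Atwater factors 4/9/4 kcal/g (the package
  computes kcal from grams rather than a food database); calorie fractions
  are 0 for zero-calorie events.
* **Activity alignment**: per 15-min interval, EE and acceleration are
  summed (extensive) and heart rate averaged (intensive); empty intervals
  are flagged missing.
* **Sleep join**: each grid row takes the closest preceding sleep record
  ending no more than 28 h earlier, else missing.
* **Stretch selection**: an uninterrupted stretch is a maximal run of grid
  rows where glucose *and* activity are both present — a single missing
  interval breaks it (strictest reading of "no break"; diaries have no
  sampling cadence and are treated as available whenever devices are worn).
  Stretches under 24 h are dropped; subjects whose stretches total ≤ 7 days
  are excluded.
* **Splits**: glucose prediction holds out the final 72 h of available data
  (measured from the end of the last stretch); meal detection trains on the
  first 96 h and tests on the following 72 h, leaving later data unused.
  Subjects with < 4 days (glucose) or < 7 days (meal detection) are
  excluded with a warning.

## Feature engineering

90 min = 6 samples at the 15-min cadence, so lead/lag orders run 1..6; the
plain lead/lag features use the same 6 orders for symmetry. The "lagged
difference of the lead" is implemented as the 1-sample-lagged lead
difference `g(t+k-1) - g(t-1)`. Windowed SDs use ddof=1. Degenerate
constant windows resolve 0/0 ratios to the neutral 1 (SD ratio) and the
relative SD to 0; max/min ratios are safe because glucose is strictly
positive. Rows whose windows would cross a stretch boundary carry missing
values — never imputed; the tree models route missing values natively.

The 72 glucose predictors are (4 kcal totals + 3 fractions) × 7 windows
(sums / meal-row means) + (ee, acn) sums × 7 + ahr means × 7 + 2 sleep
columns. Fraction means average only over in-window rows that carry a meal
(0 on empty support — fractions are undefined without intake). The
regression target is the natural log of glucose; log base e is also used
for the log-lead differences. Subject one-hot indicators are appended for
the regression and are not counted among the 72. Meal-detection features
are CGM-only by default; a config switch (`meal_include_activity`) appends
the per-interval activity columns.

## Modeling

XGBoost (`tree_method=hist`, single thread) for both tasks:
`binary:logistic` for meal classification (decision threshold 0.5, no class
re-weighting; imbalance is surfaced by reporting sensitivity and
specificity separately) and `reg:squarederror` on log-glucose.

* **RFE**: 10-fold CV (stratified for classification; row-random folds —
  subject/time-blocked CV is exposed but defaults off), fixed 100 rounds,
  library-default hyperparameters. Each step drops the lowest-gain 20% of
  remaining features (≥1; zero-gain ties break toward later columns) down
  to a single feature. The selected subset is the smallest whose CV error
  is within 10% of the best subset's error (error scale:
  `err <= 1.10 * best`).
* **Tuning** (selected features only, folds drawn from an independent
  seeded stream): classification uses an exhaustive grid over max_depth
  {3,6} × eta {0.1,0.3} × min_child_weight {1,5} × subsample {0.8,1.0};
  regression uses 60 random draws with max_depth ∈ [2,8], eta log-uniform
  [0.03,0.3], min_child_weight ∈ [1,10], subsample and colsample_bytree ∈
  [0.6,1]. Grid extents and draw count were sized for desk-scale runtime.
  Ties break toward smaller max_depth, then earlier candidate order.
* **Determinism**: training rows are lexicographically sorted before
  fitting, so results are invariant to input row order; all CV partitions
  and random draws are seeded. Bundles serialize to a single JSON archive
  (raw booster + feature/parameter/seed sidecar) and reload to bit-identical
  predictions.

## Attribution

Shapley values use the path-dependent polynomial-time tree algorithm
(EXTEND/UNWIND path recursion over every root-leaf path), implemented in
float64 over the booster's raw JSON tree dump. Child cover fractions are
renormalized by the sibling sum, and input values are routed with float32
comparison semantics to match the booster bit-for-bit, so local accuracy
(base value + contributions = raw margin) holds to ~1e-15 — the raw margin
is re-evaluated in float64 from the same trees. Tests cross-check the
implementation against the booster's own `pred_contribs` (float32, 1e-4
tolerance) and against brute-force Shapley subset enumeration on small
forests.

Importance groups: windows ≤ 3 h are short-term, 8 h/24 h long-term; ee and
ahr form the cardiometabolic group, acn the activity groups, kcal/fraction
features the nutrition groups; sleep columns and subject indicators form
their own groups. Unmapped feature names raise — there is no silent "other"
bucket. Peaks are strict local maxima (plateaus attributed to their first
index; series edges excluded) above Q3 + IQR of the subject's glucose
series, with type-7 quantiles; all qualifying maxima count (no minimum peak
distance). Peaks are located on observed glucose over the training rows and
explained through the model rows at the same timestamps; subject indicators
are eligible top-5 candidates (they represent the subject-specific
intercept). Ties in |contribution| break by column order.

## Evaluation

Classification metrics are pooled over rows and reported with per-subject
min–max ranges; a subject with no positives (negatives) has undefined
sensitivity (specificity) and is excluded from that range with a warning.
Regression MAE is computed per subject on the mmol/L scale after
exponentiating the log-scale predictions; the summary is the unweighted
mean ± SD (ddof=1) across subjects. Bland–Altman uses differences
predicted − observed, with the 2.5th/97.5th percentiles (type 7) as limits
of agreement rather than ±1.96 SD.

## Problem sizes and runtime choices

The acceptance script simulates a 12-subject × 14-day cohort (the scale at
which all signal-recovery properties are assessed) and runs both full
analyses with the method's own settings (10 folds, 100 rounds, 60 random
draws). The signal-recovery experiment (10 seeded replicates, strong carb
coupling, activity effect disabled, default-parameter fits) caps the
attribution pass at 2,500 training rows per replicate — the grouped
mean-|Shapley| ranking it checks is insensitive to this subsampling, and
the single full analysis run explains every training row. Unit tests use
smaller cohorts and lighter CV settings where only plumbing or determinism
contracts are exercised.

## Known limitations

* The generator's additivity means interaction effects (e.g. activity ×
  meal timing) are absent; models fitted to it cannot be expected to
  transfer to real cohorts.
* Row-random CV folds leak within-subject autocorrelation across folds;
  blocked CV is available but not the default, to mirror the analysis
  design this package implements.
* The last-3-days test measures temporal generalization only within the
  same wearing period; no across-cohort validation is possible from
  synthetic data.
* Peak explanation reuses the training-row attributions; peaks in the
  held-out period are not explained.
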