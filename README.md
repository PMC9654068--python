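# glucolens

Digital-biomarker analyses for wearable metabolic time series: detecting
**eating moments** from continuous interstitial glucose, and **predicting and
explaining individual glucose levels** from diet, physical activity and sleep.

The package targets researchers working with multimodal free-living cohorts —
a CGM sensor sampling interstitial glucose every 15 minutes over ~14 days, a
timestamped food diary with macronutrient grams, a wrist-worn tracker
reporting energy expenditure (ee), acceleration counts (acn) and heart rate
(ahr), and nightly sleep records. Because such participant data are rarely
shareable, a synthetic cohort generator with known ground truth (meal-driven
glucose excursions, activity-driven dips, sleep effects, device gaps) makes
every stage of the pipeline testable end to end.

## The two analyses

**Meal detection.** Glucose dynamics around an eating moment are summarized
per 15-min grid point by 41 CGM-only features: leads/lags of order
$k = 1..6$ (spanning 90 min), lead differences $g(t{+}k)-g(t)$, log-lead
differences, lagged lead differences, windowed means/SDs of the 90-min lead,
lag and ±90-min windows, relative SDs and lead/lag ratios of SD, max and min.
A grid row is labeled positive when a carbohydrate-containing meal falls in
its 15-min interval or an adjacent one (a 30-min positive segment per meal).
A gradient-boosted tree classifier (XGBoost) is trained on the first 4 days
per subject and tested on the next 3.

**Glucose prediction.** 72 engineered predictors — 7 nutrition variables
(4 Atwater calorie totals as rolling sums, 3 calorie fractions as rolling
means) and 3 activity variables over trailing windows of 30/60/90 min and
2/3/8/24 h, plus sleep duration and deep-sleep duration — predict the
concurrent log-glucose value, with subject one-hot indicators absorbing
stable inter-individual differences. Training uses all but the last 3 days
per subject; the last 3 days are held out.

Both models pass through **recursive feature elimination** (10-fold CV, 100
boosting rounds, gain-ranked elimination of the weakest 20% per step; the
smallest subset within 10% of the best CV error is kept) and hyperparameter
search (grid search for the classifier, random search for the regressor).

**Explanation.** Per-instance attributions are exact tree-ensemble Shapley
values $\phi_{ij}$ computed with the path-dependent polynomial-time tree
algorithm in float64, satisfying local accuracy
$f(x_i) = \phi_0 + \sum_j \phi_{ij}$ to machine precision. Overall importance
is the mean absolute Shapley value per feature, aggregated into seven groups
(cardiometabolic, subject, activity short/long term, nutrition short/long
term, sleep). Per-subject glucose peaks above the Q3 + IQR threshold are
explained by their top-5 contributing features; subjects with fewer than 10
peaks are excluded from peak-level reporting. Agreement between predicted and
observed glucose is assessed with Bland–Altman bias and 2.5th/97.5th
*percentile* limits of agreement.

## Worked example

```python
from glucolens import CohortConfig, RunConfig, run_glucose

cfg = RunConfig(cohort=CohortConfig(n_subjects=4, n_days=10, seed=3),
                folds=3, rounds=30, n_random=5, seed=3)
result = run_glucose(cfg)
for split in ("train", "test"):
    m, a = result["metrics"][split], result["agreement"][split]
    print(f"{split}: MAE {m['mae_mean']:.3f} (+/-{m['mae_sd']:.3f}) mmol/L, "
          f"bias {a['bias']:.3f}, LoA ({a['loa_lower']:.3f}, {a['loa_upper']:.3f})")
print(result["group_importance"][["group", "percent"]].round(1).to_string(index=False))
```

prints (exactly reproducible with these seeds):

```
train: MAE 0.275 (+/-0.049) mmol/L, bias -0.023, LoA (-0.859, 0.719)
test: MAE 0.246 (+/-0.063) mmol/L, bias 0.004, LoA (-0.670, 0.683)
               group  percent
     cardiometabolic      0.0
             subject     24.9
  activity_long_term      0.0
 activity_short_term      0.0
 nutrition_long_term      7.6
nutrition_short_term     67.5
               sleep      0.0
```

i.e. held-out glucose is predicted to within ~0.25 mmol/L on average with
negligible bias, and — as this synthetic cohort's glucose is driven almost
entirely by carbohydrate intake — short-term nutrition features dominate the
attribution, with the subject intercept absorbing baseline differences.

The same run is available from the shell:

```bash
glucolens run-glucose --seed 3 --out scratch/demo
glucolens run-mealdetect --seed 3
```

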