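"""Feature engineering for the two analyses.

Meal detection uses CGM-only features computed per uninterrupted stretch:
leads and lags of order 1-6 (covering 90 min at the 15-min cadence),
differences / log-differences / lagged differences of the leads, windowed
means and standard deviations of the 90-min lead, lag and the combined
+/-90-min window, relative standard deviations, and lead/lag ratios of sd,
maximum and minimum.  Rows whose window would cross a stretch boundary
carry missing values — nothing is imputed.  A grid row is labeled positive
when a carbohydrate-containing meal falls in its 15-min interval or in an
immediately adjacent one, so an isolated meal yields a 30-min positive
segment (15 min before and after the eating moment).

Glucose prediction uses 72 engineered predictors: 7 nutrition variables
(4 calorie totals, rolled as sums; 3 calorie fractions, rolled as means
over meal-carrying rows) and 3 activity variables (energy expenditure and
acceleration rolled as sums, heart rate as mean) over trailing windows of
30/60/90 min and 2/3/8/24 h, plus the joined sleep duration and deep-sleep
duration.  The regression target is the natural log of glucose.  Subject
one-hot indicator columns may be appended; they are not counted among the
72.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "CGM_FEATURES",
    "GLUCOSE_FEATURES",
    "WINDOWS",
    "build_cgm_features",
    "build_meal_labels",
    "build_glucose_features",
    "add_subject_indicators",
]

K_ORDERS = range(1, 7)  # 1..6 lead/lag orders = 90 min at 15-min cadence

CGM_FEATURES: list[str] = (
    [f"lag{k}" for k in K_ORDERS]
    + [f"lead{k}" for k in K_ORDERS]
    + [f"dlead{k}" for k in K_ORDERS]
    + [f"dloglead{k}" for k in K_ORDERS]
    + [f"lagdlead{k}" for k in K_ORDERS]
    + [
        "sd_lead90",
        "mean_lead90",
        "sd_lag90",
        "mean_lag90",
        "sd_pm90",
        "mean_pm90",
        "rsd_lead90",
        "rsd_lag90",
        "ratio_sd",
        "ratio_max",
        "ratio_min",
    ]
)

#: trailing rolling windows: label -> number of 15-min samples
WINDOWS: list[tuple[str, int]] = [
    ("30m", 2),
    ("60m", 4),
    ("90m", 6),
    ("2h", 8),
    ("3h", 12),
    ("8h", 32),
    ("24h", 96),
]

_NUTRITION_SUM = ["kcal_total", "kcal_carb", "kcal_fat", "kcal_protein"]
_NUTRITION_MEAN = ["frac_carb", "frac_fat", "frac_protein"]
_ACTIVITY_SUM = ["energy_expenditure", "acceleration"]
_ACTIVITY_MEAN = ["heart_rate"]

_SHORT = {"ee": "energy_expenditure", "acn": "acceleration", "ahr": "heart_rate"}
_ABBREV = {v: k for k, v in _SHORT.items()}

GLUCOSE_FEATURES: list[str] = (
    [f"{base}_{w}_sum" for base in _NUTRITION_SUM for w, _ in WINDOWS]
    + [f"{base}_{w}_mean" for base in _NUTRITION_MEAN for w, _ in WINDOWS]
    + [f"{_ABBREV[base]}_{w}_sum" for base in _ACTIVITY_SUM for w, _ in WINDOWS]
    + [f"{_ABBREV[base]}_{w}_mean" for base in _ACTIVITY_MEAN for w, _ in WINDOWS]
    + ["sleep_duration", "deep_sleep_duration"]
)
assert len(GLUCOSE_FEATURES) == 72


def _windowed(values: np.ndarray, offsets: list[int]) -> np.ndarray:
    """Stack shifted copies of ``values``; out-of-range positions are NaN."""
    n = len(values)
    cols = []
    for off in offsets:
        col = np.full(n, np.nan)
        if off >= 0:
            if off < n:
                col[: n - off] = values[off:]
        else:
            if -off < n:
                col[-off:] = values[: n + off]
        cols.append(col)
    return np.column_stack(cols)


def _cgm_features_one(g: np.ndarray) -> pd.DataFrame:
    n = len(g)
    out: dict[str, np.ndarray] = {}
    shift = lambda off: _windowed(g, [off])[:, 0]  # noqa: E731
    for k in K_ORDERS:
        out[f"lag{k}"] = shift(-k)
        out[f"lead{k}"] = shift(k)
        out[f"dlead{k}"] = shift(k) - g
        out[f"dloglead{k}"] = np.log(shift(k)) - np.log(g)
        out[f"lagdlead{k}"] = shift(k - 1) - shift(-1)
    lead = _windowed(g, [k for k in K_ORDERS])  # t+1 .. t+6
    lag = _windowed(g, [-k for k in K_ORDERS])  # t-1 .. t-6
    pm = _windowed(g, list(range(-6, 7)))  # t-6 .. t+6 (13 samples)
    # strict windows: any boundary-crossing sample leaves the feature missing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["sd_lead90"] = np.std(lead, axis=1, ddof=1)
        out["mean_lead90"] = np.mean(lead, axis=1)
        out["sd_lag90"] = np.std(lag, axis=1, ddof=1)
        out["mean_lag90"] = np.mean(lag, axis=1)
        out["sd_pm90"] = np.std(pm, axis=1, ddof=1)
        out["mean_pm90"] = np.mean(pm, axis=1)
        max_lead = np.max(lead, axis=1)
        max_lag = np.max(lag, axis=1)
        min_lead = np.min(lead, axis=1)
        min_lag = np.min(lag, axis=1)
    # glucose is strictly positive so the means/extrema never vanish;
    # constant windows give 0/0 in the sd ratio, resolved to the neutral 1
    out["rsd_lead90"] = out["sd_lead90"] / out["mean_lead90"]
    out["rsd_lag90"] = out["sd_lag90"] / out["mean_lag90"]
    num, den = out["sd_lead90"], out["sd_lag90"]
    ratio = np.full(n, np.nan)
    both_zero = (num == 0) & (den == 0)
    ratio[both_zero] = 1.0
    ok = den > 0
    ratio[ok] = num[ok] / den[ok]
    nan_rows = np.isnan(num) | np.isnan(den)
    ratio[nan_rows] = np.nan
    out["ratio_sd"] = ratio
    out["ratio_max"] = max_lead / max_lag
    out["ratio_min"] = min_lead / min_lag
    return pd.DataFrame(out, columns=CGM_FEATURES)


def build_cgm_features(aligned: pd.DataFrame) -> pd.DataFrame:
    """CGM meal-detection features, computed independently per stretch.

    Returns a frame indexed like ``aligned`` with the :data:`CGM_FEATURES`
    columns; rows outside any stretch, and rows whose lead/lag windows would
    cross a stretch boundary, hold NaN.  Stretches shorter than 13 samples
    (no row has both 90-min windows) produce all-missing rows with a warning.
    """
    out = pd.DataFrame(np.nan, index=aligned.index, columns=CGM_FEATURES)
    for sid, sub in aligned.dropna(subset=["stretch_id"]).groupby("stretch_id"):
        if len(sub) < 13:
            warnings.warn(f"stretch {sid}: <13 samples, all meal-detection features missing")
            continue
        feats = _cgm_features_one(sub["glucose"].to_numpy(dtype=float))
        out.loc[sub.index, :] = feats.to_numpy()
    return out


def build_meal_labels(aligned: pd.DataFrame, meals: pd.DataFrame, grid_step_min: int = 15) -> pd.Series:
    """Binary eating-moment labels on the aligned grid.

    A row is positive when a meal event containing any carbohydrates starts
    in its interval or in the interval of an immediately adjacent row, so an
    isolated carb meal marks a 30-min positive segment.  Events falling
    outside a subject's grid span are ignored with a warning.
    """
    step = pd.Timedelta(minutes=grid_step_min)
    label = np.zeros(len(aligned), dtype=bool)
    aligned_pos = pd.Series(np.arange(len(aligned)), index=aligned.index)
    for subj, sub in aligned.groupby("subject_id", sort=True):
        m = meals[(meals["subject_id"] == subj) & (meals["kcal_carb"] > 0)]
        if m.empty:
            continue
        grid = pd.DatetimeIndex(sub["timestamp"])
        binned = m["timestamp"].dt.floor(step)
        inside = binned.isin(grid)
        if (~inside).any():
            warnings.warn(f"subject {subj}: {(~inside).sum()} meal event(s) outside the grid span ignored")
        hit = grid.get_indexer(pd.DatetimeIndex(binned[inside]))
        base = aligned_pos[sub.index].to_numpy()
        for off in (-1, 0, 1):
            pos = hit + off
            pos = pos[(pos >= 0) & (pos < len(base))]
            label[base[pos]] = True
    return pd.Series(label, index=aligned.index, name="label")


def _rolling_sum(x: pd.Series, n: int) -> pd.Series:
    return x.rolling(n, min_periods=n).sum()


def build_glucose_features(aligned: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """The 72 engineered predictors and the log-glucose target.

    Rolling windows are trailing (they end at, and include, the current row)
    and are computed independently per stretch so they never cross a stretch
    boundary; rows with insufficient in-stretch history are missing.  Calorie
    fractions are averaged only over rows where a meal is present in the
    window (0 with no intake).  Returns ``(X, y)`` indexed like ``aligned``;
    rows outside any stretch are all-missing.
    """
    X = pd.DataFrame(np.nan, index=aligned.index, columns=GLUCOSE_FEATURES)
    y = pd.Series(np.nan, index=aligned.index, name="log_glucose")
    for _, sub in aligned.dropna(subset=["stretch_id"]).groupby("stretch_id"):
        has_meal = sub["has_meal"].astype(float)
        for w, n in WINDOWS:
            for base in _NUTRITION_SUM:
                X.loc[sub.index, f"{base}_{w}_sum"] = _rolling_sum(sub[base], n).to_numpy()
            den = _rolling_sum(has_meal, n)
            for base in _NUTRITION_MEAN:
                num = _rolling_sum(sub[base] * has_meal, n)
                with np.errstate(invalid="ignore"):
                    val = np.where(den.to_numpy() > 0, num.to_numpy() / den.to_numpy(), 0.0)
                val = np.where(np.isnan(den.to_numpy()), np.nan, val)
                X.loc[sub.index, f"{base}_{w}_mean"] = val
            for base in _ACTIVITY_SUM:
                X.loc[sub.index, f"{_ABBREV[base]}_{w}_sum"] = _rolling_sum(sub[base], n).to_numpy()
            for base in _ACTIVITY_MEAN:
                X.loc[sub.index, f"{_ABBREV[base]}_{w}_mean"] = (
                    sub[base].rolling(n, min_periods=n).mean().to_numpy()
                )
        X.loc[sub.index, "sleep_duration"] = sub["sleep_duration"].to_numpy()
        X.loc[sub.index, "deep_sleep_duration"] = sub["deep_sleep_duration"].to_numpy()
        y.loc[sub.index] = np.log(sub["glucose"].to_numpy(dtype=float))
    return X, y


def add_subject_indicators(X: pd.DataFrame, subject_ids: pd.Series) -> pd.DataFrame:
    """Append one-hot subject indicator columns (``subj_<id>``)."""
    dummies = pd.get_dummies(subject_ids, prefix="subj", dtype=float)
    dummies.index = X.index
    return pd.concat([X, dummies], axis=1)
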