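"""Gradient-boosted tree models with recursive feature elimination.

Both analyses use XGBoost.  Feature selection is recursive feature
elimination driven by the booster's *gain* importance: starting from the
full feature set, 10-fold cross-validated performance is recorded with
default hyperparameters and a fixed 100 boosting rounds, the lowest-gain
20% of the remaining features are dropped, and the loop continues down to
one feature.  The smallest subset whose cross-validated error is within
10% of the best subset's error is selected.

Hyperparameters of the final models are tuned on the selected features:
grid search minimizing the classification error for meal detection, random
search (60 draws) minimizing the mean absolute error of the log-glucose
target for glucose regression, both with 10-fold cross-validation.  Fold
partitions for RFE and tuning are drawn from independent seeded streams.

Training rows are put into a canonical order (lexicographic in target and
features) before fitting, so predictions are invariant to the row order of
the input.
"""

from __future__ import annotations

import base64
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "RfeResult",
    "ModelBundle",
    "rfe_select",
    "tune_hyperparams",
    "fit",
    "predict",
    "save_bundle",
    "load_bundle",
    "SchemaError",
    "DEFAULT_PARAMS",
    "DEFAULT_GRID",
]

log = logging.getLogger("glucolens")

TASKS = ("meal_classification", "glucose_regression")

#: xgboost defaults used during RFE (no tuning at that stage)
DEFAULT_PARAMS: dict = {
    "max_depth": 6,
    "eta": 0.3,
    "min_child_weight": 1.0,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
}

#: small documented grid for the meal-detection classifier
DEFAULT_GRID: dict[str, list] = {
    "max_depth": [3, 6],
    "eta": [0.1, 0.3],
    "min_child_weight": [1.0, 5.0],
    "subsample": [0.8, 1.0],
}

#: ranges for the regression random search
RANDOM_RANGES = {
    "max_depth": (2, 8),  # integer, inclusive
    "eta": (0.03, 0.3),  # log-uniform
    "min_child_weight": (1.0, 10.0),
    "subsample": (0.6, 1.0),
    "colsample_bytree": (0.6, 1.0),
}


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the fitted bundle."""


@dataclass
class RfeResult:
    """Trace of the elimination path and the selected feature subset."""

    sizes: list[int]
    cv_mean: list[float]  # classification error or MAE per subset size
    cv_sd: list[float]
    feature_sets: list[list[str]]
    selected: list[str] = field(default_factory=list)
    best_size: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_features": self.sizes, "cv_mean": self.cv_mean, "cv_sd": self.cv_sd}
        )


@dataclass
class ModelBundle:
    """A fitted tree ensemble with everything needed to reuse it."""

    task: str
    booster: xgb.Booster
    features: list[str]
    params: dict
    rounds: int
    gain_importance: dict[str, float]
    seed: int
    fingerprint: str


def _task_params(task: str, params: dict, seed: int) -> dict:
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    full = dict(params)
    full.update(
        {
            "seed": seed,
            "nthread": 1,
            "tree_method": "hist",
            "verbosity": 0,
        }
    )
    if task == "meal_classification":
        full["objective"] = "binary:logistic"
        full.setdefault("base_score", 0.5)
    else:
        full["objective"] = "reg:squarederror"
    return full


def _check_target(task: str, y: np.ndarray) -> None:
    if task == "meal_classification":
        uniq = np.unique(y[~np.isnan(y)])
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("classification target must be binary (0/1)")


def _folds(task: str, y: np.ndarray, n_folds: int, seed: int):
    if task == "meal_classification":
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(len(y)), y))
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(len(y))))


def _fold_score(task: str, booster: xgb.Booster, dtest: xgb.DMatrix, y: np.ndarray) -> float:
    pred = booster.predict(dtest)
    if task == "meal_classification":
        return float(np.mean((pred > 0.5).astype(float) != y))
    return float(np.mean(np.abs(pred - y)))


def _cv_score(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    task: str,
    params: dict,
    rounds: int,
    folds,
    seed: int,
) -> tuple[float, float]:
    scores = []
    full = _task_params(task, params, seed)
    for tr, te in folds:
        dtr = xgb.DMatrix(X[tr], label=y[tr], feature_names=feature_names, missing=np.nan)
        dte = xgb.DMatrix(X[te], label=y[te], feature_names=feature_names, missing=np.nan)
        bst = xgb.train(full, dtr, num_boost_round=rounds)
        scores.append(_fold_score(task, bst, dte, y[te]))
    return float(np.mean(scores)), float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0


def _gain_ranking(
    X: np.ndarray, y: np.ndarray, feature_names: list[str], task: str, rounds: int, seed: int
) -> list[str]:
    """Features sorted by ascending gain (never-split features first)."""
    d = xgb.DMatrix(X, label=y, feature_names=feature_names, missing=np.nan)
    bst = xgb.train(_task_params(task, DEFAULT_PARAMS, seed), d, num_boost_round=rounds)
    gain = bst.get_score(importance_type="gain")
    order = {name: i for i, name in enumerate(feature_names)}
    # ties (e.g. several zero-gain features) resolved by reversed column
    # order so the later column is eliminated first
    return sorted(feature_names, key=lambda f: (gain.get(f, 0.0), -order[f]))


def rfe_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    task: str,
    n_folds: int = 10,
    rounds: int = 100,
    drop_frac: float = 0.2,
    within: float = 0.10,
    seed: int = 0,
) -> RfeResult:
    """Recursive feature elimination with cross-validated performance tracking.

    At each iteration the model is cross-validated on the current subset with
    default hyperparameters and a fixed number of rounds, then the lowest-gain
    ``drop_frac`` of the remaining features (at least one) are eliminated.
    The smallest subset whose cross-validated error is within ``within``
    (relative) of the best subset's error is selected.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    y = np.asarray(y, dtype=float)
    _check_target(task, y)
    folds = _folds(task, y, n_folds, seed)
    Xv = X.to_numpy(dtype=float)
    names = list(X.columns)
    current = names
    result = RfeResult([], [], [], [])
    while True:
        cols = [names.index(f) for f in current]
        mean, sd = _cv_score(Xv[:, cols], y, current, task, DEFAULT_PARAMS, rounds, folds, seed)
        result.sizes.append(len(current))
        result.cv_mean.append(mean)
        result.cv_sd.append(sd)
        result.feature_sets.append(list(current))
        log.info("rfe task=%s size=%d cv=%.5f (+/-%.5f)", task, len(current), mean, sd)
        if len(current) == 1:
            break
        ranked = _gain_ranking(Xv[:, cols], y, current, task, rounds, seed)
        n_drop = max(1, int(drop_frac * len(current)))
        dropped = set(ranked[:n_drop])
        current = [f for f in current if f not in dropped]
    best = min(result.cv_mean)
    result.best_size = result.sizes[int(np.argmin(result.cv_mean))]
    eligible = [
        (size, feats)
        for size, mean, feats in zip(result.sizes, result.cv_mean, result.feature_sets)
        if mean <= (1.0 + within) * best + 1e-12
    ]
    size, feats = min(eligible, key=lambda t: t[0])
    result.selected = feats
    log.info("rfe task=%s selected %d features (best cv=%.5f)", task, size, best)
    return result


def _random_draw(rng: np.random.Generator) -> dict:
    lo, hi = RANDOM_RANGES["eta"]
    return {
        "max_depth": int(rng.integers(RANDOM_RANGES["max_depth"][0], RANDOM_RANGES["max_depth"][1] + 1)),
        "eta": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "min_child_weight": float(rng.uniform(*RANDOM_RANGES["min_child_weight"])),
        "subsample": float(rng.uniform(*RANDOM_RANGES["subsample"])),
        "colsample_bytree": float(rng.uniform(*RANDOM_RANGES["colsample_bytree"])),
    }


def tune_hyperparams(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    task: str,
    n_folds: int = 10,
    rounds: int = 100,
    search: str | None = None,
    n_random: int = 60,
    grid: dict[str, list] | None = None,
    seed: int = 0,
) -> dict:
    """Tune hyperparameters on the selected features.

    Classification uses exhaustive grid search over :data:`DEFAULT_GRID`
    minimizing the cross-validated classification error; regression uses
    ``n_random`` random draws from :data:`RANDOM_RANGES` minimizing the
    cross-validated MAE.  Ties break toward lower model complexity (smaller
    ``max_depth``), then earlier candidate order.
    """
    y = np.asarray(y, dtype=float)
    _check_target(task, y)
    if search is None:
        search = "grid" if task == "meal_classification" else "random"
    if search == "grid":
        g = grid or DEFAULT_GRID
        keys = list(g)
        candidates = [dict(zip(keys, combo)) for combo in itertools.product(*(g[k] for k in keys))]
    else:
        rng = np.random.default_rng(seed)
        candidates = [_random_draw(rng) for _ in range(n_random)]
    folds = _folds(task, y, n_folds, seed + 1)
    Xv = X.to_numpy(dtype=float)
    names = list(X.columns)
    scored = []
    for i, cand in enumerate(candidates):
        params = dict(DEFAULT_PARAMS)
        params.update(cand)
        mean, _ = _cv_score(Xv, y, names, task, params, rounds, folds, seed)
        scored.append((mean, params.get("max_depth", 6), i, params))
        log.info("tune task=%s candidate=%d cv=%.5f", task, i, mean)
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored[0][3]


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)] + [y]
    return np.lexsort(keys)


def fit(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    task: str,
    params: dict | None = None,
    rounds: int = 100,
    seed: int = 0,
) -> ModelBundle:
    """Fit the final ensemble; rows with a missing target are dropped."""
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    if (~keep).any():
        log.info("fit: dropped %d rows with missing target", int((~keep).sum()))
    X = X.loc[keep]
    y = y[keep]
    _check_target(task, y)
    params = dict(DEFAULT_PARAMS if params is None else params)
    Xv = X.to_numpy(dtype=float)
    order = _canonical_order(Xv, y)
    names = list(X.columns)
    d = xgb.DMatrix(Xv[order], label=y[order], feature_names=names, missing=np.nan)
    booster = xgb.train(_task_params(task, params, seed), d, num_boost_round=rounds)
    gain = booster.get_score(importance_type="gain")
    importance = {f: float(gain.get(f, 0.0)) for f in names}
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(Xv[order]).tobytes())
    h.update(np.ascontiguousarray(y[order]).tobytes())
    return ModelBundle(
        task=task,
        booster=booster,
        features=names,
        params=params,
        rounds=rounds,
        gain_importance=importance,
        seed=seed,
        fingerprint=h.hexdigest(),
    )


def predict(bundle: ModelBundle, X: pd.DataFrame) -> np.ndarray:
    """Predict from a bundle: eating-moment probabilities in [0, 1] for the
    classifier, glucose in mmol/L (back-transformed from the log scale) for
    the regressor."""
    missing = [f for f in bundle.features if f not in X.columns]
    extra = [c for c in X.columns if c not in bundle.features]
    if missing or extra:
        raise SchemaError(f"feature mismatch: missing={missing}, unexpected={extra}")
    d = xgb.DMatrix(
        X[bundle.features].to_numpy(dtype=float), feature_names=bundle.features, missing=np.nan
    )
    raw = bundle.booster.predict(d)
    if bundle.task == "glucose_regression":
        return np.exp(raw)
    return raw


def save_bundle(bundle: ModelBundle, path) -> None:
    """Serialize a bundle to a single JSON archive."""
    raw = bytes(bundle.booster.save_raw(raw_format="ubj"))
    doc = {
        "task": bundle.task,
        "features": bundle.features,
        "params": bundle.params,
        "rounds": bundle.rounds,
        "gain_importance": bundle.gain_importance,
        "seed": bundle.seed,
        "fingerprint": bundle.fingerprint,
        "booster_ubj_b64": base64.b64encode(raw).decode("ascii"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_bundle(path) -> ModelBundle:
    with open(path) as fh:
        doc = json.load(fh)
    booster = xgb.Booster()
    booster.load_model(bytearray(base64.b64decode(doc.pop("booster_ubj_b64"))))
    return ModelBundle(booster=booster, **doc)
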