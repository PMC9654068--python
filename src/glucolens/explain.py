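"""Per-instance additive attribution and peak-level model interpretation.

Attributions are exact tree-ensemble Shapley values computed with the
path-dependent polynomial-time tree algorithm: for each instance the
recursion walks every root-leaf path, tracking for each feature on the path
the fraction of training weight (node cover) that would flow down when the
feature is unknown versus the indicator of the instance's own branch, and
accumulates each leaf's value into the features on its path with the
exactly-computed Shapley permutation weights.  Everything is evaluated in
float64 from the booster's dumped tree structure, so local accuracy —
base value plus the sum of contributions equals the raw margin — holds to
machine precision.  The raw margin itself is re-evaluated in float64 from
the same trees.

On top of the attributions this module builds the overall importance
report (mean absolute contribution per feature, aggregated into seven
domain groups), detects per-subject glucose peaks with the Q3 + IQR
threshold rule, and tabulates how often each feature appears among the
top-5 contributors at those peaks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .modeling import ModelBundle

__all__ = [
    "ShapExplanation",
    "PeakSet",
    "compute_attributions",
    "overall_importance",
    "find_peaks_q3iqr",
    "peak_feature_frequency",
    "feature_group",
    "GROUPS",
    "UnmappedFeatureError",
    "UnsupportedModelError",
]

GROUPS = [
    "cardiometabolic",
    "subject",
    "activity_long_term",
    "activity_short_term",
    "nutrition_long_term",
    "nutrition_short_term",
    "sleep",
]

_SHORT_WINDOWS = {"30m", "60m", "90m", "2h", "3h"}
_LONG_WINDOWS = {"8h", "24h"}


class UnmappedFeatureError(ValueError):
    """A feature name does not belong to any known importance group."""


class UnsupportedModelError(TypeError):
    """Attribution requires a tree-ensemble bundle."""


@dataclass
class ShapExplanation:
    """Additive per-row, per-feature contributions on the model's raw scale
    (log-glucose for the regressor), plus the base value (the cover-weighted
    expected model output) and the float64 raw margin of each row."""

    values: np.ndarray  # (n_rows, n_features)
    base_value: float
    feature_names: list[str]
    raw_margin: np.ndarray  # (n_rows,)
    row_index: pd.Index | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names, index=self.row_index)


@dataclass
class PeakSet:
    """Per-subject glucose peaks above the Q3 + IQR threshold."""

    subject_id: str
    threshold: float  # mmol/L
    q1: float
    q3: float
    peak_positions: np.ndarray  # positional indices into the subject's series
    n_peaks: int
    excluded: bool  # True when fewer than the minimum number of peaks


# ---------------------------------------------------------------------------
# tree extraction


def _extract_trees(bundle: ModelBundle):
    """Flatten the booster's trees into arrays for the jitted kernels.

    Parses the booster's raw JSON model, which stores the exact float32
    split thresholds and leaf values (a leaf's value sits in
    ``split_conditions``; ``sum_hessian`` is the node cover).
    """
    if not isinstance(bundle, ModelBundle) or not hasattr(bundle.booster, "save_raw"):
        raise UnsupportedModelError("attribution requires a fitted tree-ensemble bundle")
    model = json.loads(bytes(bundle.booster.save_raw(raw_format="json")))
    learner = model["learner"]
    trees = learner["gradient_booster"]["model"]["trees"]
    base_score = float(learner["learner_model_param"]["base_score"])
    objective = learner.get("objective", {}).get("name", "")
    if "logistic" in objective:  # stored in probability space; margins are log-odds
        base_score = float(np.log(base_score / (1.0 - base_score)))

    lefts, rights, feats, threshs, defleft, values, covers, roots = [], [], [], [], [], [], [], []
    max_depth = 1
    for tree in trees:
        off = len(lefts)
        roots.append(off)
        tl = np.asarray(tree["left_children"], dtype=np.int64)
        tr = np.asarray(tree["right_children"], dtype=np.int64)
        # decimal JSON values denote float32 numbers; round-trip through
        # float32 so threshold comparisons match the booster bit-for-bit
        cond = np.asarray(tree["split_conditions"], dtype=np.float32).astype(np.float64)
        is_leaf = tl < 0
        lefts.extend(np.where(is_leaf, -1, tl + off).tolist())
        rights.extend(np.where(is_leaf, -1, tr + off).tolist())
        feats.extend(np.where(is_leaf, -1, np.asarray(tree["split_indices"], dtype=np.int64)).tolist())
        threshs.extend(np.where(is_leaf, 0.0, cond).tolist())
        defleft.extend(np.asarray(tree["default_left"], dtype=np.int64).tolist())
        values.extend(np.where(is_leaf, cond, 0.0).tolist())
        covers.extend(np.asarray(tree["sum_hessian"], dtype=np.float64).tolist())
        # path length in nodes, iteratively from the parent pointers
        d = np.ones(len(tl), dtype=int)
        for i in range(len(tl)):
            if tl[i] >= 0:
                d[tl[i]] = d[i] + 1
                d[tr[i]] = d[i] + 1
        max_depth = max(max_depth, int(d.max()))
    return (
        np.asarray(lefts, dtype=np.int64),
        np.asarray(rights, dtype=np.int64),
        np.asarray(feats, dtype=np.int64),
        np.asarray(threshs, dtype=np.float64),
        np.asarray(defleft, dtype=np.int64),
        np.asarray(values, dtype=np.float64),
        np.asarray(covers, dtype=np.float64),
        np.asarray(roots, dtype=np.int64),
        max_depth,
        base_score,
    )


# ---------------------------------------------------------------------------
# jitted kernels


@njit(cache=False)
def _expected_value(node, left, right, value, cover, out):
    if left[node] < 0:
        out[node] = value[node]
        return value[node]
    el = _expected_value(left[node], left, right, value, cover, out)
    er = _expected_value(right[node], left, right, value, cover, out)
    cl, cr = cover[left[node]], cover[right[node]]
    e = (cl * el + cr * er) / (cl + cr)
    out[node] = e
    return e


@njit(cache=False)
def _extend(F, Z, O, W, row, ud, pz, po, pi):
    F[row, ud] = pi
    Z[row, ud] = pz
    O[row, ud] = po
    W[row, ud] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        W[row, i + 1] += po * W[row, i] * (i + 1.0) / (ud + 1.0)
        W[row, i] = pz * W[row, i] * (ud - i) / (ud + 1.0)


@njit(cache=False)
def _unwind(F, Z, O, W, row, ud, path_index):
    one = O[row, path_index]
    zero = Z[row, path_index]
    nxt = W[row, ud]
    for j in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = W[row, j]
            W[row, j] = nxt * (ud + 1.0) / ((j + 1.0) * one)
            nxt = tmp - W[row, j] * zero * (ud - j) / (ud + 1.0)
        else:
            W[row, j] = W[row, j] * (ud + 1.0) / (zero * (ud - j))
    for j in range(path_index, ud):
        F[row, j] = F[row, j + 1]
        Z[row, j] = Z[row, j + 1]
        O[row, j] = O[row, j + 1]


@njit(cache=False)
def _unwound_sum(F, Z, O, W, row, ud, path_index):
    one = O[row, path_index]
    zero = Z[row, path_index]
    nxt = W[row, ud]
    total = 0.0
    for j in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (ud + 1.0) / ((j + 1.0) * one)
            total += tmp
            nxt = W[row, j] - tmp * zero * (ud - j) / (ud + 1.0)
        else:
            total += W[row, j] / (zero * (ud - j) / (ud + 1.0))
    return total


@njit(cache=False)
def _recurse(node, level, ud, pz, po, pi, x, left, right, feat, thresh, defleft, value, cover, F, Z, O, W, phi):
    if level > 0:
        for i in range(ud):
            F[level, i] = F[level - 1, i]
            Z[level, i] = Z[level - 1, i]
            O[level, i] = O[level - 1, i]
            W[level, i] = W[level - 1, i]
    _extend(F, Z, O, W, level, ud, pz, po, pi)
    if left[node] < 0:
        for i in range(1, ud + 1):
            w = _unwound_sum(F, Z, O, W, level, ud, i)
            phi[F[level, i]] += w * (O[level, i] - Z[level, i]) * value[node]
    else:
        sf = feat[node]
        xv = x[sf]
        if np.isnan(xv):
            hot = left[node] if defleft[node] == 1 else right[node]
        else:
            hot = left[node] if xv < thresh[node] else right[node]
        cold = right[node] if hot == left[node] else left[node]
        csum = cover[left[node]] + cover[right[node]]
        hot_zero = cover[hot] / csum
        cold_zero = cover[cold] / csum
        iz = 1.0
        io = 1.0
        k = 0
        found = False
        while k <= ud:
            if F[level, k] == sf:
                found = True
                break
            k += 1
        if found:
            iz = Z[level, k]
            io = O[level, k]
            _unwind(F, Z, O, W, level, ud, k)
            ud -= 1
        _recurse(hot, level + 1, ud + 1, hot_zero * iz, io, sf, x, left, right, feat, thresh, defleft, value, cover, F, Z, O, W, phi)
        _recurse(cold, level + 1, ud + 1, cold_zero * iz, 0.0, sf, x, left, right, feat, thresh, defleft, value, cover, F, Z, O, W, phi)


@njit(cache=False)
def _margin_one(x, left, right, feat, thresh, defleft, value, roots):
    total = 0.0
    for t in range(len(roots)):
        node = roots[t]
        while left[node] >= 0:
            xv = x[feat[node]]
            if np.isnan(xv):
                node = left[node] if defleft[node] == 1 else right[node]
            else:
                node = left[node] if xv < thresh[node] else right[node]
        total += value[node]
    return total


@njit(cache=False)
def _shap_all(X, left, right, feat, thresh, defleft, value, cover, roots, max_depth, n_features):
    n = X.shape[0]
    phi = np.zeros((n, n_features))
    margins = np.zeros(n)
    size = max_depth + 3
    F = np.zeros((size, size), dtype=np.int64)
    Z = np.zeros((size, size))
    O = np.zeros((size, size))
    W = np.zeros((size, size))
    for r in range(n):
        x = X[r]
        for t in range(len(roots)):
            _recurse(roots[t], 0, 0, 1.0, 1.0, -1, x, left, right, feat, thresh, defleft, value, cover, F, Z, O, W, phi[r])
        margins[r] = _margin_one(x, left, right, feat, thresh, defleft, value, roots)
    return phi, margins


# ---------------------------------------------------------------------------
# public operations


def compute_attributions(bundle: ModelBundle, X: pd.DataFrame) -> ShapExplanation:
    """Exact path-dependent tree Shapley values for every row of ``X``.

    Contributions are on the model's raw scale (log-glucose for the
    regressor, log-odds for the classifier).  Local accuracy holds:
    ``base_value + values.sum(axis=1) == raw_margin`` to float64 precision.
    """
    if not isinstance(bundle, ModelBundle):
        raise UnsupportedModelError("attribution requires a fitted tree-ensemble bundle")
    missing = [f for f in bundle.features if f not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    left, right, feat, thresh, defleft, value, cover, roots, max_depth, base_score = _extract_trees(bundle)
    # route with float32 value semantics, as the booster itself does
    Xv = np.ascontiguousarray(X[bundle.features].to_numpy(dtype=np.float32).astype(np.float64))
    phi, margins = _shap_all(
        Xv, left, right, feat, thresh, defleft, value, cover, roots, max_depth, len(bundle.features)
    )
    exp_out = np.zeros(len(left))
    base = base_score
    for root in roots:
        base += _expected_value(root, left, right, value, cover, exp_out)
    return ShapExplanation(
        values=phi,
        base_value=float(base),
        feature_names=list(bundle.features),
        raw_margin=margins + base_score,
        row_index=X.index,
    )


def feature_group(name: str) -> str:
    """Map an engineered feature name to its importance group.

    Energy expenditure and heart rate are cardiometabolic; acceleration is
    activity; calorie totals and fractions are nutrition; activity and
    nutrition split into short term (windows up to 3 h) and long term
    (8 h and 24 h); sleep columns and subject indicators form their own
    groups.  Unknown names raise (no silent "other" bucket).
    """
    if name.startswith("subj_"):
        return "subject"
    if name in ("sleep_duration", "deep_sleep_duration"):
        return "sleep"
    parts = name.split("_")
    if len(parts) >= 3:
        window, agg = parts[-2], parts[-1]
        base = "_".join(parts[:-2])
        if agg in ("sum", "mean") and (window in _SHORT_WINDOWS or window in _LONG_WINDOWS):
            horizon = "short_term" if window in _SHORT_WINDOWS else "long_term"
            if base in ("ee", "ahr"):
                return "cardiometabolic"
            if base == "acn":
                return f"activity_{horizon}"
            if base.startswith("kcal_") or base.startswith("frac_"):
                return f"nutrition_{horizon}"
    raise UnmappedFeatureError(f"feature {name!r} has no importance group")


def overall_importance(expl: ShapExplanation) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean-absolute-contribution importance, per feature and per group.

    Returns ``(per_feature, per_group)`` frames; group weights are
    percentages normalized to sum to 100.
    """
    weight = np.abs(expl.values).mean(axis=0)
    per_feature = pd.DataFrame(
        {
            "feature": expl.feature_names,
            "group": [feature_group(f) for f in expl.feature_names],
            "weight": weight,
        }
    ).sort_values("weight", ascending=False, ignore_index=True)
    grouped = per_feature.groupby("group")["weight"].sum()
    grouped = grouped.reindex(GROUPS, fill_value=0.0)
    total = grouped.sum()
    percent = grouped / total * 100.0 if total > 0 else grouped * 0.0
    per_group = pd.DataFrame({"group": grouped.index, "weight": grouped.to_numpy(), "percent": percent.to_numpy()})
    per_feature["percent"] = per_feature["weight"] / total * 100.0 if total > 0 else 0.0
    return per_feature, per_group


def find_peaks_q3iqr(
    glucose: np.ndarray | pd.Series, subject_id: str = "", min_peaks: int = 10
) -> PeakSet:
    """Strict local glucose maxima above the subject's Q3 + IQR threshold.

    Quartiles are type-7 percentiles of the full series; a peak is a value
    strictly greater than both neighbouring (differing) values, with plateaus
    attributed to their first index; series edges cannot be peaks.  Subjects
    with fewer than ``min_peaks`` peaks are flagged as excluded from
    peak-level reporting.
    """
    v = np.asarray(glucose, dtype=float)
    if len(v) < 3:
        raise ValueError("series must have at least 3 samples")
    q1, q3 = np.percentile(v, [25, 75])
    threshold = q3 + (q3 - q1)
    peaks = []
    i = 1
    n = len(v)
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1  # plateau [i, j]
        if j + 1 < n and v[i] > v[i - 1] and v[i] > v[j + 1] and v[i] > threshold:
            peaks.append(i)
        i = j + 1
    pos = np.asarray(peaks, dtype=int)
    return PeakSet(
        subject_id=subject_id,
        threshold=float(threshold),
        q1=float(q1),
        q3=float(q3),
        peak_positions=pos,
        n_peaks=len(pos),
        excluded=len(pos) < min_peaks,
    )


def peak_feature_frequency(
    expl: ShapExplanation,
    peak_rows_by_subject: dict[str, np.ndarray],
    peak_sets: dict[str, PeakSet] | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """How often each feature ranks among the top-``k`` contributors at peaks.

    ``peak_rows_by_subject`` maps each subject to positional row indices of
    the explanation matrix corresponding to that subject's glucose peaks.
    Subjects flagged excluded in ``peak_sets`` are omitted.  Ties in
    \\|contribution\\| break by column order.  Returns a tidy frame
    (subject_id, feature, count).
    """
    records = []
    for subj in sorted(peak_rows_by_subject):
        if peak_sets is not None and subj in peak_sets and peak_sets[subj].excluded:
            continue
        rows = np.asarray(peak_rows_by_subject[subj], dtype=int)
        counts: dict[str, int] = {}
        for r in rows:
            mag = np.abs(expl.values[r])
            top = np.argsort(-mag, kind="stable")[: min(k, len(mag))]
            for j in top:
                name = expl.feature_names[j]
                counts[name] = counts.get(name, 0) + 1
        for name, cnt in sorted(counts.items(), key=lambda t: (-t[1], t[0])):
            records.append({"subject_id": subj, "feature": name, "count": cnt})
    return pd.DataFrame(records, columns=["subject_id", "feature", "count"])
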