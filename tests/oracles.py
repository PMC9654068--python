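"""Independent brute-force reference implementations used as test oracles.

Everything here is written against the *definitions* (explicit window
materialization, explicit quartiles, explicit subset enumeration) and stays
independent of the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def cgm_features_bruteforce(g: np.ndarray) -> dict[str, np.ndarray]:
    """Meal-detection features computed row by row with explicit windows."""
    n = len(g)
    out: dict[str, list] = {}

    def val(i):
        return g[i] if 0 <= i < n else np.nan

    def window(lo, hi, i):  # values g[i+lo] .. g[i+hi]
        return [val(i + o) for o in range(lo, hi + 1)]

    cols = (
        [f"lag{k}" for k in range(1, 7)]
        + [f"lead{k}" for k in range(1, 7)]
        + [f"dlead{k}" for k in range(1, 7)]
        + [f"dloglead{k}" for k in range(1, 7)]
        + [f"lagdlead{k}" for k in range(1, 7)]
        + [
            "sd_lead90", "mean_lead90", "sd_lag90", "mean_lag90", "sd_pm90", "mean_pm90",
            "rsd_lead90", "rsd_lag90", "ratio_sd", "ratio_max", "ratio_min",
        ]
    )
    for c in cols:
        out[c] = []

    def sd(vals):
        if any(math.isnan(v) for v in vals):
            return np.nan
        m = sum(vals) / len(vals)
        return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))

    def mean(vals):
        if any(math.isnan(v) for v in vals):
            return np.nan
        return sum(vals) / len(vals)

    for i in range(n):
        for k in range(1, 7):
            out[f"lag{k}"].append(val(i - k))
            out[f"lead{k}"].append(val(i + k))
            out[f"dlead{k}"].append(val(i + k) - g[i])
            out[f"dloglead{k}"].append(
                math.log(val(i + k)) - math.log(g[i]) if not math.isnan(val(i + k)) else np.nan
            )
            out[f"lagdlead{k}"].append(val(i + k - 1) - val(i - 1))
        lead = window(1, 6, i)
        lag = window(-6, -1, i)
        pm = window(-6, 6, i)
        out["sd_lead90"].append(sd(lead))
        out["mean_lead90"].append(mean(lead))
        out["sd_lag90"].append(sd(lag))
        out["mean_lag90"].append(mean(lag))
        out["sd_pm90"].append(sd(pm))
        out["mean_pm90"].append(mean(pm))
        sl, ml = sd(lead), mean(lead)
        sg, mg = sd(lag), mean(lag)
        out["rsd_lead90"].append(sl / ml if not math.isnan(sl) else np.nan)
        out["rsd_lag90"].append(sg / mg if not math.isnan(sg) else np.nan)
        if math.isnan(sl) or math.isnan(sg):
            out["ratio_sd"].append(np.nan)
        elif sl == 0.0 and sg == 0.0:
            out["ratio_sd"].append(1.0)
        elif sg == 0.0:
            out["ratio_sd"].append(np.nan)
        else:
            out["ratio_sd"].append(sl / sg)
        out["ratio_max"].append(
            max(lead) / max(lag) if not (math.isnan(mean(lead)) or math.isnan(mean(lag))) else np.nan
        )
        out["ratio_min"].append(
            min(lead) / min(lag) if not (math.isnan(mean(lead)) or math.isnan(mean(lag))) else np.nan
        )
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def rolling_bruteforce(values: np.ndarray, n: int, how: str, meal_mask: np.ndarray | None = None) -> np.ndarray:
    """Trailing-window aggregate materializing each window explicitly."""
    out = []
    for i in range(len(values)):
        if i - n + 1 < 0:
            out.append(np.nan)
            continue
        w = values[i - n + 1 : i + 1]
        if how == "sum":
            out.append(float(np.sum(w)))
        elif how == "mean":
            out.append(float(np.mean(w)))
        elif how == "meal_mean":
            m = meal_mask[i - n + 1 : i + 1]
            out.append(float(w[m].mean()) if m.any() else 0.0)
        else:
            raise ValueError(how)
    return np.asarray(out)


def quantile_type7(sorted_vals: np.ndarray, q: float) -> float:
    """Type-7 (linear interpolation) percentile of pre-sorted values."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return float(sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo]))


def peaks_bruteforce(v: np.ndarray) -> tuple[float, list[int]]:
    """Q3+IQR threshold and strict-local-maximum scan (plateau-first)."""
    s = np.sort(np.asarray(v, dtype=float))
    q1 = quantile_type7(s, 0.25)
    q3 = quantile_type7(s, 0.75)
    thr = q3 + (q3 - q1)
    peaks = []
    n = len(v)
    for i in range(1, n - 1):
        if v[i] <= v[i - 1]:
            continue
        # walk over any plateau starting at i
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and v[i] > v[j + 1] and v[i] > thr:
            peaks.append(i)
    return thr, peaks


def stretches_bruteforce(ok: np.ndarray, min_rows: int) -> list[tuple[int, int]]:
    """All maximal runs of True of length >= min_rows, by linear scan."""
    runs = []
    start = None
    for i, flag in enumerate(list(ok) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_rows:
                runs.append((start, i))
            start = None
    return runs


def shapley_bruteforce(trees, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact Shapley values by subset enumeration over all features.

    ``trees`` is the flattened array tuple (left, right, feat, thresh,
    defleft, value, cover, roots).  The value function of a feature subset S
    routes x down each tree, following x's branch for features in S and
    averaging children by their cover fraction otherwise.
    """
    left, right, feat, thresh, defleft, value, cover, roots = trees

    def expect(node, S):
        if left[node] < 0:
            return value[node]
        f = feat[node]
        if f in S:
            xv = x[f]
            if math.isnan(xv):
                child = left[node] if defleft[node] == 1 else right[node]
            else:
                child = left[node] if xv < thresh[node] else right[node]
            return expect(child, S)
        cl, cr = cover[left[node]], cover[right[node]]
        return (cl * expect(left[node], S) + cr * expect(right[node], S)) / (cl + cr)

    def v_of(S):
        return sum(expect(r, S) for r in roots)

    phi = np.zeros(n_features)
    for i in range(n_features):
        rest = [f for f in range(n_features) if f != i]
        for mask in range(1 << len(rest)):
            S = frozenset(rest[j] for j in range(len(rest)) if mask >> j & 1)
            w = (
                math.factorial(len(S))
                * math.factorial(n_features - len(S) - 1)
                / math.factorial(n_features)
            )
            phi[i] += w * (v_of(S | {i}) - v_of(S))
    return phi
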