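"""Evaluation surface for the two analyses.

Classification: pooled and per-subject accuracy, sensitivity and
specificity at a fixed probability threshold, with per-subject min-max
ranges.  Regression: per-subject mean absolute error on the mmol/L scale
(predictions are back-transformed from the log scale before scoring) with
the unweighted across-subject mean and SD.  Agreement: Bland-Altman bias
(mean of predicted - observed) with 2.5th/97.5th *percentile* limits of
agreement rather than the parametric +/-1.96 SD band.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "classification_metrics",
    "mae_summary",
    "bland_altman",
    "plot_goodness_of_fit",
    "plot_bland_altman",
]


def _rates(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    tp = float(np.sum(pred & truth))
    tn = float(np.sum(~pred & ~truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    n = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / n if n else np.nan,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


def classification_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray | pd.Series,
    threshold: float = 0.5,
) -> dict:
    """Pooled and per-subject classification metrics with min-max ranges.

    Subjects without positives (or without negatives) have an undefined
    sensitivity (or specificity) and are excluded from that metric's range
    with a warning.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels).astype(bool)
    subject_ids = np.asarray(subject_ids)
    if len(probabilities) != len(labels) or len(labels) != len(subject_ids):
        raise ValueError("probabilities, labels and subject_ids must have equal length")
    pred = probabilities > threshold
    out = _rates(pred, labels)
    per_subject: dict[str, dict[str, float]] = {}
    for subj in sorted(np.unique(subject_ids).tolist()):
        m = subject_ids == subj
        r = _rates(pred[m], labels[m])
        for key in ("sensitivity", "specificity"):
            if np.isnan(r[key]):
                warnings.warn(f"subject {subj}: {key} undefined, excluded from range")
        per_subject[subj] = r
    ranges = {}
    for key in ("accuracy", "sensitivity", "specificity"):
        vals = [r[key] for r in per_subject.values() if not np.isnan(r[key])]
        ranges[key] = (min(vals), max(vals)) if vals else (np.nan, np.nan)
    out.update(
        {
            "per_subject": per_subject,
            "range": ranges,
            "n_rows": int(len(labels)),
            "n_subjects": int(len(per_subject)),
            "threshold": threshold,
        }
    )
    return out


def mae_summary(
    predicted: np.ndarray, observed: np.ndarray, subject_ids: np.ndarray | pd.Series
) -> dict:
    """Per-subject MAE (mmol/L) with the unweighted mean and SD across subjects."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    subject_ids = np.asarray(subject_ids)
    err = np.abs(predicted - observed)
    per_subject = {
        str(subj): float(err[subject_ids == subj].mean())
        for subj in sorted(np.unique(subject_ids).tolist())
    }
    vals = np.array(list(per_subject.values()))
    return {
        "per_subject": per_subject,
        "mae_mean": float(vals.mean()),
        "mae_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "n_rows": int(len(err)),
        "n_subjects": int(len(per_subject)),
    }


def bland_altman(predicted: np.ndarray, observed: np.ndarray) -> dict:
    """Agreement between predicted and observed values.

    Differences are ``predicted - observed``; the limits of agreement are the
    2.5th and 97.5th percentiles of the differences (type-7 interpolation).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(predicted) != len(observed):
        raise ValueError("paired arrays must have equal length")
    if len(predicted) < 2:
        raise ValueError("need at least 2 pairs")
    d = predicted - observed
    lo, hi = np.percentile(d, [2.5, 97.5])
    return {"bias": float(d.mean()), "loa_lower": float(lo), "loa_upper": float(hi), "n": int(len(d))}


def plot_goodness_of_fit(timestamps, observed, predicted, subject_id: str, path) -> None:
    """Observed vs predicted glucose trace for one subject (optional plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(timestamps, observed, lw=1, label="observed")
    ax.plot(timestamps, predicted, lw=1, label="predicted")
    ax.set_ylabel("glucose (mmol/L)")
    ax.set_title(f"subject {subject_id}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(predicted, observed, path) -> None:
    """Difference-vs-mean agreement plot with percentile limits (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    stats = bland_altman(predicted, observed)
    d = predicted - observed
    m = (predicted + observed) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=4, alpha=0.3)
    for y, style in ((stats["bias"], "-"), (stats["loa_lower"], "--"), (stats["loa_upper"], "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of predicted and observed (mmol/L)")
    ax.set_ylabel("predicted - observed (mmol/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
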