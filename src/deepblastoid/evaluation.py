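"""Classification metrics and inter-rater agreement statistics.

Covers what a microwell-classification study reports: the 5x5 confusion
matrix, top-k accuracy, one-vs-rest precision/recall (sensitivity),
specificity and F1 per class, and chance-corrected agreement between
multiple human annotators (Fleiss' kappa for complete rating tables,
Krippendorff's alpha — nominal metric — which also tolerates missing
ratings).

Zero-denominator metrics (e.g. precision of a never-predicted class) are
reported as NaN and excluded from macro averages, never silently zero.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import ClassLabel, CLASS_NAMES, N_CLASSES, encode_labels

__all__ = [
    "confusion_matrix",
    "topk_accuracy",
    "class_metrics",
    "fleiss_kappa",
    "krippendorff_alpha",
]


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence) -> np.ndarray:
    """5x5 count matrix, rows = true class, cols = predicted class."""
    y = encode_labels(true_labels)
    p = encode_labels(predicted_labels)
    if len(y) != len(p):
        raise ValueError("true and predicted labels must have equal length")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (y, p), 1)
    return cm


def topk_accuracy(true_labels: Sequence, proba: np.ndarray, k: int = 1) -> float:
    """Fraction of items whose true class is among the k highest-probability
    classes. Probability ties rank the lower class index first, matching the
    argmax convention of prediction."""
    if not 1 <= k <= N_CLASSES:
        raise ValueError(f"k must lie in 1..{N_CLASSES}")
    y = encode_labels(true_labels)
    proba = np.asarray(proba, dtype=np.float64)
    if proba.shape != (len(y), N_CLASSES):
        raise ValueError("probability matrix shape must be (n, 5)")
    order = np.argsort(-proba, axis=1, kind="stable")  # stable: ties -> lowest index first
    return float((order[:, :k] == y[:, None]).any(axis=1).mean())


def class_metrics(cm: np.ndarray) -> dict:
    """One-vs-rest metrics from a confusion matrix.

    Returns a dict with overall ``accuracy``, ``macro_f1``, ``micro_f1``
    and a ``per_class`` DataFrame (precision, recall aka sensitivity,
    specificity, f1, support). Undefined ratios are NaN and are skipped by
    the macro average.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain at least one item")
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _ratio(num, den):
        return np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = np.where(
        np.isnan(precision) | np.isnan(recall) | ((precision + recall) == 0),
        np.nan,
        2 * precision * recall / np.where((precision + recall) > 0, precision + recall, 1),
    )
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
            "support": cm.sum(axis=1),
        },
        index=list(CLASS_NAMES),
    )
    accuracy = float(tp.sum() / total)
    macro_f1 = float(np.nanmean(f1)) if not np.all(np.isnan(f1)) else math.nan
    micro_f1 = accuracy  # single-label multiclass: micro F1 == accuracy
    return {
        "accuracy": accuracy,
        "macro_f1": macro_f1,
        "micro_f1": micro_f1,
        "per_class": per_class,
    }


# ---------------------------------------------------------------------------
# inter-rater agreement


def _as_rating_array(table) -> np.ndarray:
    """items x raters array of class codes, NaN marking missing ratings."""
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy()
    arr = np.asarray(table, dtype=object)
    if arr.ndim != 2:
        raise ValueError("rating table must be items x raters")
    out = np.full(arr.shape, np.nan)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if v is None or (isinstance(v, (float, np.floating)) and math.isnan(v)):
                continue
            if isinstance(v, (float, np.floating)):
                v = int(v)
            out[i, j] = int(ClassLabel.from_any(v))
    return out


def fleiss_kappa(table) -> float:
    """Fleiss' kappa for an items x raters table of categorical labels.

    kappa = (Pbar - Pbar_e) / (1 - Pbar_e), with Pbar the mean pairwise
    agreement per item and Pbar_e the chance agreement from the pooled
    category marginals. Requires the same number of ratings on every item
    (no missing cells). Returns NaN when Pbar_e = 1 (all raters always use
    one category: agreement is undefined, not perfect).
    """
    arr = _as_rating_array(table)
    if np.isnan(arr).any():
        raise ValueError("Fleiss' kappa requires a complete rating table")
    n_items, n_raters = arr.shape
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    counts = np.zeros((n_items, N_CLASSES), dtype=np.float64)
    for c in range(N_CLASSES):
        counts[:, c] = (arr == c).sum(axis=1)
    p_cat = counts.sum(axis=0) / (n_items * n_raters)
    p_item = (np.sum(counts * (counts - 1), axis=1)) / (n_raters * (n_raters - 1))
    p_bar = p_item.mean()
    p_e = float(np.sum(p_cat**2))
    if p_e == 1.0:
        return math.nan
    return float((p_bar - p_e) / (1.0 - p_e))


def krippendorff_alpha(table, metric: str = "nominal") -> float:
    """Krippendorff's alpha via the coincidence matrix (nominal metric).

    alpha = 1 - Do/De. Items with fewer than 2 ratings are dropped;
    missing cells are allowed. Returns NaN when De = 0 (no disagreement is
    even possible).
    """
    if metric != "nominal":
        raise ValueError("only the nominal metric is implemented")
    arr = _as_rating_array(table)
    coincidence = np.zeros((N_CLASSES, N_CLASSES), dtype=np.float64)
    for row in arr:
        vals = row[~np.isnan(row)].astype(int)
        m = len(vals)
        if m < 2:
            continue
        # pairable values: each ordered pair of distinct rating slots
        for i_a in range(m):
            for i_b in range(m):
                if i_a != i_b:
                    coincidence[vals[i_a], vals[i_b]] += 1.0 / (m - 1)
    n_total = coincidence.sum()
    if n_total <= 0:
        raise ValueError("need at least one item with >= 2 ratings")
    n_c = coincidence.sum(axis=1)
    d_o = n_total - np.trace(coincidence)  # observed disagreement (nominal)
    d_e = (n_total**2 - np.sum(n_c**2)) / (n_total - 1) if n_total > 1 else 0.0
    if d_e == 0:
        return math.nan
    return float(1.0 - d_o / d_e)
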