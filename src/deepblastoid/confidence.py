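"""Confidence-Rate (CR) statistic and selective-prediction triage.

For a 5-class score vector ``P`` the CR is computed by normalizing
``p_i = P_i / sum(P)``, taking the mean ``mu`` and population standard
deviation ``sigma`` of the five normalized values, standardizing the
maximum, ``Z = (p_max - mu) / sigma``, and squashing through a sigmoid,
``CR = 1 / (1 + exp(-Z))``. CR measures how far the winning class stands
out from the rest of the probability vector: a uniform vector gives
CR = 0.5 (the Z -> 0 limit of the degenerate sigma = 0 case), a one-hot
vector gives the maximum 1/(1+e^-2) ~ 0.8808. For five classes Z is
bounded by sqrt(5-1) = 2, attained exactly when the four losing
probabilities are equal.

Predictions with CR below a threshold (0.8 by default) are flagged for
human expert review; the rest are auto-accepted. Sweeping the threshold
trades retained data volume against accuracy on the retained subset.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import ClassLabel, CLASS_NAMES, N_CLASSES

__all__ = [
    "CR_MAX",
    "DEFAULT_THRESHOLD",
    "TriageDecision",
    "TradeoffPoint",
    "confidence_rate",
    "confidence_rates",
    "triage",
    "tradeoff_curve",
]

#: Upper bound of CR for 5 classes: sigmoid of Z_max = sqrt(4) = 2.
CR_MAX: float = 1.0 / (1.0 + np.exp(-2.0))
DEFAULT_THRESHOLD: float = 0.8


@dataclasses.dataclass(frozen=True)
class TriageDecision:
    """Routing of one prediction at a CR threshold."""

    predicted_label: ClassLabel
    cr: float
    routed: str  # "auto_accept" | "flag_for_review"
    threshold_used: float


@dataclasses.dataclass(frozen=True)
class TradeoffPoint:
    """One point of the accuracy-vs-data-volume sweep.

    ``retained_accuracy`` is None when no item clears the threshold
    (undefined, not zero); ``empty`` flags that case.
    """

    threshold: float
    retained_fraction: float
    retained_accuracy: float | None
    empty: bool = False


def confidence_rate(P: Sequence[float]) -> float:
    """CR of a single 5-class score vector (see module docstring).

    Scores need not be normalized (CR is scale-invariant); they must be
    nonnegative with a positive sum.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class scores, got shape {P.shape}")
    if np.any(P < 0):
        raise ValueError("class scores must be nonnegative")
    total = P.sum()
    if total <= 0:
        raise ValueError("class scores must have a positive sum")
    p = P / total
    mu = p.mean()
    sigma = np.sqrt(np.mean((p - mu) ** 2))  # population form over all 5
    if sigma <= 1e-12:
        # uniform to machine precision: Z -> 0 limit (the raw ratio of two
        # round-off-sized quantities is numerically meaningless)
        return 0.5
    z = (p.max() - mu) / sigma
    return float(1.0 / (1.0 + np.exp(-z)))


def confidence_rates(proba: np.ndarray) -> np.ndarray:
    """Vectorized CR over rows of an (n, 5) score matrix."""
    proba = np.asarray(proba, dtype=np.float64)
    if proba.ndim != 2 or proba.shape[1] != N_CLASSES:
        raise ValueError(f"expected (n, {N_CLASSES}) score matrix")
    if np.any(proba < 0):
        raise ValueError("class scores must be nonnegative")
    totals = proba.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every row must have a positive sum")
    p = proba / totals
    mu = p.mean(axis=1)
    sigma = np.sqrt(np.mean((p - mu[:, None]) ** 2, axis=1))
    ok = sigma > 1e-12
    z = np.where(ok, (p.max(axis=1) - mu) / np.where(ok, sigma, 1.0), 0.0)
    return 1.0 / (1.0 + np.exp(-z))


def triage(
    proba: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    predictions: Sequence | None = None,
) -> tuple[list[TriageDecision], dict]:
    """Route each prediction by its CR at the given threshold.

    Items with ``cr >= threshold`` are auto-accepted, the rest flagged for
    review. Predictions default to the row argmax (ties to the lowest
    class index). Returns the decisions and a partition summary whose
    counts sum to the input count.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    proba = np.asarray(proba, dtype=np.float64)
    crs = confidence_rates(proba)
    if predictions is None:
        codes = np.argmax(proba, axis=1)
    else:
        codes = np.array([int(ClassLabel.from_any(p)) for p in predictions])
    decisions = [
        TriageDecision(
            ClassLabel(int(c)),
            float(cr),
            "auto_accept" if cr >= threshold else "flag_for_review",
            threshold,
        )
        for c, cr in zip(codes, crs)
    ]
    n_auto = int(np.sum(crs >= threshold))
    summary = {
        "n": len(decisions),
        "auto_accept": n_auto,
        "flag_for_review": len(decisions) - n_auto,
        "threshold": threshold,
    }
    return decisions, summary


def triage_frame(proba: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Triage as a tidy table: predicted_label, p_A..p_W, cr, routed."""
    decisions, _ = triage(proba, threshold)
    df = pd.DataFrame(np.asarray(proba, dtype=np.float64), columns=[f"p_{c}" for c in CLASS_NAMES])
    df.insert(0, "predicted_label", [d.predicted_label.name for d in decisions])
    df["cr"] = [d.cr for d in decisions]
    df["routed"] = [d.routed for d in decisions]
    return df


def tradeoff_curve(
    proba: np.ndarray,
    true_labels: Sequence,
    thresholds: Sequence[float],
) -> list[TradeoffPoint]:
    """Accuracy on the auto-accepted subset versus retained data volume.

    At threshold 0 everything is retained, so retained accuracy equals the
    overall top-1 accuracy; as the threshold rises the retained fraction is
    non-increasing. An empty retained set yields an undefined (None)
    accuracy flagged with ``empty=True``.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("need at least one threshold")
    proba = np.asarray(proba, dtype=np.float64)
    y = np.array([int(ClassLabel.from_any(l)) for l in true_labels])
    if len(y) != len(proba):
        raise ValueError("labels must align with probability vectors")
    crs = confidence_rates(proba)
    correct = np.argmax(proba, axis=1) == y
    points = []
    for t in sorted(thresholds):
        keep = crs >= t
        frac = float(keep.mean())
        if keep.any():
            points.append(TradeoffPoint(float(t), frac, float(correct[keep].mean())))
        else:
            points.append(TradeoffPoint(float(t), 0.0, None, empty=True))
    return points


def tradeoff_frame(points: list[TradeoffPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": [p.threshold for p in points],
            "retained_fraction": [p.retained_fraction for p in points],
            "retained_accuracy": [p.retained_accuracy for p in points],
        }
    )
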