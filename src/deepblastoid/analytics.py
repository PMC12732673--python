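"""Experiment-level analytics over classified microwell tiles.

Once every microwell in a condition is classified, the biology reads out
as class frequencies: cavitation efficiency is the combined frequency of
classes A, B and C (structures with a cavity), and the empty ratio is the
frequency of class W (empty microwells), which doubles as a seeding-
density quality control — the sparser the seeding, the more empty wells.

The density calibration models that relationship as log-linear,
``ln(empty_ratio) = a + b * density`` with ``b < 0`` — the form a Poisson
zero-count argument suggests — and inverts it to predict cells-per-
microwell from an observed empty ratio.

Group comparisons (e.g. a dose gradient with replicate experiments per
dose) use one-way ANOVA followed by Tukey's HSD multiple-comparison test,
both computed from their closed forms; two groups also get an unpaired
two-tailed t-test.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labels import ClassLabel, CLASS_NAMES, N_CLASSES, encode_labels

__all__ = [
    "ExperimentSummary",
    "DensityCalibration",
    "summarize",
    "anova_oneway",
    "calibrate_density",
    "predict_density",
    "compare_groups",
]

CAVITY_CLASSES = (ClassLabel.A, ClassLabel.B, ClassLabel.C)


@dataclasses.dataclass(frozen=True)
class ExperimentSummary:
    """Per-condition class frequencies and derived readouts."""

    condition: str
    n_images: int
    frequencies: tuple[float, float, float, float, float]
    cavitation_efficiency: float
    empty_ratio: float

    def to_dict(self) -> dict:
        d = {"condition": self.condition, "n_images": self.n_images}
        d.update({f"freq_{c}": f for c, f in zip(CLASS_NAMES, self.frequencies)})
        d["cavitation_efficiency"] = self.cavitation_efficiency
        d["empty_ratio"] = self.empty_ratio
        return d


def summarize(predictions: Sequence, condition: str = "") -> ExperimentSummary:
    """Class frequencies, cavitation efficiency (freq A+B+C) and empty ratio
    (freq W) for one condition's predicted labels."""
    codes = encode_labels(predictions)
    n = len(codes)
    if n == 0:
        raise ValueError("need at least one prediction")
    counts = np.bincount(codes, minlength=N_CLASSES)
    freqs = counts / n
    return ExperimentSummary(
        condition=condition,
        n_images=n,
        frequencies=tuple(float(f) for f in freqs),
        cavitation_efficiency=float(freqs[[int(c) for c in CAVITY_CLASSES]].sum()),
        empty_ratio=float(freqs[int(ClassLabel.W)]),
    )


# ---------------------------------------------------------------------------
# seeding-density calibration


@dataclasses.dataclass(frozen=True)
class DensityCalibration:
    """Fitted log-linear map ln(empty_ratio) = intercept + slope * density.

    ``slope`` is negative: denser seeding leaves fewer empty microwells.
    ``domain`` is the density range of the calibration pairs.
    """

    intercept: float
    slope: float
    domain: tuple[float, float]

    def empty_ratio(self, density: float) -> float:
        return float(np.exp(self.intercept + self.slope * density))


def calibrate_density(pairs: Sequence[tuple[float, float]]) -> DensityCalibration:
    """Fit the log-linear calibration from (density, empty_ratio) pairs.

    Needs >= 2 pairs with distinct densities and ratios in (0, 1); a
    non-negative fitted slope (empty ratio failing to decrease with
    density) is rejected as non-monotone.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 calibration pairs")
    d = np.asarray([p[0] for p in pairs], dtype=np.float64)
    r = np.asarray([p[1] for p in pairs], dtype=np.float64)
    if np.unique(d).size < 2:
        raise ValueError("calibration densities must not all be identical")
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("empty ratios must lie strictly in (0, 1)")
    slope, intercept = np.polyfit(d, np.log(r), 1)
    if slope >= 0:
        raise ValueError(
            f"fit rejected: slope {slope:.4g} >= 0 — empty ratio does not decrease with density"
        )
    return DensityCalibration(float(intercept), float(slope), (float(d.min()), float(d.max())))


def predict_density(cal: DensityCalibration, empty_ratio: float) -> float:
    """Invert the calibration: cells-per-microwell from an observed empty
    ratio. Monotone decreasing in the empty ratio."""
    if not 0 < empty_ratio < 1:
        raise ValueError("empty_ratio must lie strictly in (0, 1)")
    return float((math.log(empty_ratio) - cal.intercept) / cal.slope)


# ---------------------------------------------------------------------------
# group comparison


def anova_oneway(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> dict:
    """One-way ANOVA from the closed-form sum-of-squares decomposition.

    Accepts a mapping condition -> values or a plain sequence of groups.
    Returns ss_between/ss_within, degrees of freedom, F and the p-value
    from the F distribution. Zero within-group variance leaves F undefined
    (NaN) when the means are equal, infinite when they differ.
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    return _anova_oneway(groups)


def _anova_oneway(groups: list[np.ndarray]) -> dict:
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n - k
    msb = ssb / df_b
    msw = ssw / df_w if df_w > 0 else math.nan
    if msw == 0:
        # all groups internally constant: F undefined unless means differ
        f = math.inf if ssb > 0 else math.nan
        p = 0.0 if ssb > 0 else math.nan
    else:
        f = msb / msw
        p = float(stats.f.sf(f, df_b, df_w))
    return {
        "ss_between": ssb,
        "ss_within": ssw,
        "df_between": df_b,
        "df_within": df_w,
        "F": f,
        "p": p,
    }


def _tukey_hsd(groups: list[np.ndarray], names: list[str], msw: float, df_w: int) -> pd.DataFrame:
    """All-pairs Tukey HSD with studentized-range p-values."""
    rows = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = float(gi.mean() - gj.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
            if se == 0 or not np.isfinite(msw):
                q, p = math.nan, math.nan
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            rows.append({"group_a": names[i], "group_b": names[j], "mean_diff": diff, "q": q, "p_adj": p})
    return pd.DataFrame(rows)


def compare_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA plus Tukey HSD over per-replicate values by condition.

    Parameters
    ----------
    groups:
        Mapping condition -> replicate values (e.g. per-batch cavitation
        efficiencies). Needs >= 2 groups with >= 2 replicates each.

    Returns
    -------
    dict with the ANOVA decomposition (``ss_between``, ``ss_within``,
    ``df_between``, ``df_within``, ``F``, ``p``), a ``tukey`` DataFrame of
    pairwise adjusted comparisons, and for exactly two groups also
    ``t_statistic`` / ``t_p`` from an unpaired two-tailed t-test. A zero
    within-group variance with equal means leaves F as NaN (undefined).
    """
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=np.float64) for name in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 replicates")
    res = _anova_oneway(arrays)
    msw = res["ss_within"] / res["df_within"] if res["df_within"] > 0 else math.nan
    res["tukey"] = _tukey_hsd(arrays, names, msw, res["df_within"])
    if len(arrays) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        res["t_statistic"] = float(t)
        res["t_p"] = float(p)
    return res
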