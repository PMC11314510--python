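"""ROC construction, AUC, Index-of-Union cutoffs and the sensitivity rule.

The classification rule throughout is ``score >= threshold ⇒ threatened``.
Candidate thresholds are the observed score values plus the endpoints 0 and
1, so rankings ("the third-best cutoff") are finite and reproducible.

The Index of Union scores a cutoff c by ``IU(c) = |Se(c) − AUC| +
|Sp(c) − AUC|`` (smaller is better): the optimum is the point whose
sensitivity and specificity are jointly closest to the overall AUC.
Because the purpose of the risk models is to catch truly threatened
species, the IU optimum is overridden when its sensitivity falls below a
floor (default 0.70): the ranking is walked from the top and the first
cutoff meeting the floor is chosen instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_SENSITIVITY = 0.70


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class CutoffSelection:
    """Chosen cutoff plus everything needed to audit the choice."""

    roc: list[RocPoint]
    auc: float
    iu_ranking: pd.DataFrame  # columns threshold, iu, sensitivity, specificity
    chosen_cutoff: float
    rule_applied: str  # "iu_optimal" or "sensitivity_override"
    min_sensitivity: float
    warning: str = ""


def roc_curve(scores, labels) -> list[RocPoint]:
    """ROC points at every observed score plus the {0, 1} endpoints."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    thresholds = np.unique(np.concatenate([s, [0.0, 1.0]]))
    points = [
        RocPoint(
            threshold=float(t),
            sensitivity=float(np.mean(pos >= t)),
            specificity=float(np.mean(neg < t)),
        )
        for t in thresholds
    ]
    return points


def auc(roc: list[RocPoint]) -> float:
    """Trapezoidal area under (1−specificity, sensitivity).

    Equals the concordance probability (ties counted ½) because every
    distinct score is a threshold; the (0, 0) corner is appended if the
    top threshold does not reach it.
    """
    fpr = np.array([1.0 - p.specificity for p in roc])
    tpr = np.array([p.sensitivity for p in roc])
    order = np.lexsort((tpr, fpr))  # ties in FPR must ascend in TPR
    fpr, tpr = fpr[order], tpr[order]
    if fpr[0] > 0 or tpr[0] > 0:
        fpr, tpr = np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])
    if fpr[-1] < 1 or tpr[-1] < 1:
        fpr, tpr = np.concatenate([fpr, [1.0]]), np.concatenate([tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def concordance_auc(scores, labels) -> float:
    """Brute-force pairwise concordance with ties = ½ (test oracle)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def index_of_union(roc: list[RocPoint], auc_value: float) -> pd.DataFrame:
    """Rank cutoffs ascending by IU.

    Ties break first by smaller |Se − Sp|, then by lower threshold.
    """
    rows = [
        {
            "threshold": p.threshold,
            "iu": abs(p.sensitivity - auc_value) + abs(p.specificity - auc_value),
            "sensitivity": p.sensitivity,
            "specificity": p.specificity,
            "balance": abs(p.sensitivity - p.specificity),
        }
        for p in roc
    ]
    frame = pd.DataFrame(rows).sort_values(
        ["iu", "balance", "threshold"], kind="stable", ignore_index=True
    )
    return frame.drop(columns="balance")


def select_cutoff(
    ranking: pd.DataFrame, min_sensitivity: float = DEFAULT_MIN_SENSITIVITY
) -> tuple[float, str, str]:
    """Walk the IU ranking; take the first cutoff with Se ≥ the floor.

    Returns (cutoff, rule, warning).  If no ranked cutoff reaches the floor,
    the IU optimum is returned with a warning.
    """
    if ranking.empty:
        raise ValueError("empty cutoff ranking")
    qualifying = ranking[ranking["sensitivity"] >= min_sensitivity]
    if qualifying.empty:
        row = ranking.iloc[0]
        return (
            float(row["threshold"]),
            "iu_optimal",
            f"no cutoff reaches sensitivity {min_sensitivity}; IU optimum kept",
        )
    row = qualifying.iloc[0]
    rule = "iu_optimal" if row.name == ranking.index[0] else "sensitivity_override"
    return float(row["threshold"]), rule, ""


def choose_cutoff(
    scores, labels, min_sensitivity: float = DEFAULT_MIN_SENSITIVITY
) -> CutoffSelection:
    """End-to-end: ROC → AUC → IU ranking → sensitivity-aware choice."""
    roc = roc_curve(scores, labels)
    a = auc(roc)
    ranking = index_of_union(roc, a)
    cutoff, rule, warning = select_cutoff(ranking, min_sensitivity)
    return CutoffSelection(
        roc=roc, auc=a, iu_ranking=ranking, chosen_cutoff=cutoff,
        rule_applied=rule, min_sensitivity=min_sensitivity, warning=warning,
    )


def two_graph_roc(roc: list[RocPoint]) -> tuple[pd.DataFrame, float | None]:
    """Long-format Se/Sp-vs-threshold table plus the Se = Sp crossing.

    The crossing threshold is located by linear interpolation between the
    two ROC points where Se − Sp changes sign; ``None`` when the curves do
    not cross inside the threshold range.
    """
    pts = sorted(roc, key=lambda p: p.threshold)
    table = pd.DataFrame(
        {
            "threshold": [p.threshold for p in pts],
            "sensitivity": [p.sensitivity for p in pts],
            "specificity": [p.specificity for p in pts],
        }
    )
    gap = table["sensitivity"] - table["specificity"]
    crossing = None
    for i in range(len(gap) - 1):
        g0, g1 = gap.iloc[i], gap.iloc[i + 1]
        if g0 == 0:
            crossing = float(table["threshold"].iloc[i])
            break
        if g0 * g1 < 0:
            t0, t1 = table["threshold"].iloc[i], table["threshold"].iloc[i + 1]
            crossing = float(t0 + (t1 - t0) * g0 / (g0 - g1))
            break
    return table, crossing
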