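"""Evaluation machinery: confusion-matrix metrics, the Gini index and a
single-split decision stump on the Patterson peak height.

The detection threshold study labels each case with the coordinate-space
classifier (pdb-TNCS at a rotational tolerance) and scores it with the top
non-origin Patterson peak height (percent of origin, or Z-score).  A
depth-one decision tree — an exhaustive search over candidate thresholds
minimizing the weighted Gini impurity on a random 75% training split — then
yields the operating threshold, evaluated on the held-out 25%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class LabelledCase:
    """One cohort entry: Patterson summary statistics plus the ground truth."""

    case_id: str
    height_pct: float
    zscore: float
    label: bool               # pdb-TNCS(r) ground truth
    completeness: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.height_pct <= 100.0 + 1e-9:
            raise ValueError("height_pct must lie in [0, 100]")


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, actual: np.ndarray
                         ) -> "ConfusionMatrix":
        predicted = np.asarray(predicted, dtype=bool)
        actual = np.asarray(actual, dtype=bool)
        return cls(TP=int(np.sum(predicted & actual)),
                   TN=int(np.sum(~predicted & ~actual)),
                   FP=int(np.sum(predicted & ~actual)),
                   FN=int(np.sum(~predicted & actual)))


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, false-positive rate and precision.

    ACC = (TP+TN)/total, SN = TP/(TP+FN), FPR = FP/(FP+TN),
    PREC = TP/(TP+FP).  A zero denominator yields NaN (flagged, never
    silently zero).
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "ACC": ratio(cm.TP + cm.TN, cm.total),
        "SN": ratio(cm.TP, cm.TP + cm.FN),
        "FPR": ratio(cm.FP, cm.FP + cm.TN),
        "PREC": ratio(cm.TP, cm.TP + cm.FP),
    }


def gini(scores: np.ndarray, labels: np.ndarray) -> float:
    """Gini index: twice the area between the ROC curve and its diagonal,
    i.e. 2*AUC - 1, with mid-rank handling of tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)          # mid-rank for ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return 2.0 * auc - 1.0


def _gini_impurity(labels: np.ndarray) -> float:
    if len(labels) == 0:
        return 0.0
    p = labels.mean()
    return 1.0 - p * p - (1.0 - p) * (1.0 - p)


def _best_split(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive threshold search minimizing weighted Gini impurity.

    Candidates are midpoints between consecutive sorted unique scores; ties
    resolved toward the lowest threshold for determinism.
    """
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("cannot split on a constant score")
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    n = len(scores)
    best_thr, best_imp = candidates[0], np.inf
    for thr in candidates:
        hi = scores >= thr
        imp = (hi.sum() * _gini_impurity(labels[hi]) +
               (~hi).sum() * _gini_impurity(labels[~hi])) / n
        if imp < best_imp - 1e-12:
            best_imp, best_thr = imp, thr
    return float(best_thr)


@dataclass
class ThresholdFit:
    threshold: float
    positive_above: bool      # the >= threshold side predicts TNCS
    positive_below: bool      # the < threshold side predicts TNCS
    train_size: int
    test_size: int
    confusion: ConfusionMatrix
    metrics: dict[str, float]


def fit_threshold(cases: list[LabelledCase], split: float = 0.75,
                  seed: int = 0, feature: str = "height_pct") -> ThresholdFit:
    """Fit the single-feature decision stump and evaluate held out.

    The cohort is shuffled with the given seed and divided into a training
    fraction (default 75%) used for the exhaustive threshold search and a
    held-out set on which the confusion matrix and metrics are reported.
    Only one parameter is fitted, so no cross-validation is needed.
    """
    if len(cases) < 40:
        raise ValueError("need at least 40 cases")
    scores = np.array([getattr(c, feature) for c in cases], dtype=float)
    labels = np.array([c.label for c in cases], dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_train = int(round(split * len(cases)))
    train, test = order[:n_train], order[n_train:]
    if labels[train].all() or not labels[train].any():
        raise ValueError("degenerate class balance in the training split")

    thr = _best_split(scores[train], labels[train])
    hi = scores[train] >= thr
    # each leaf predicts its training majority class (ties -> TNCS)
    positive_above = bool(labels[train][hi].mean() >= 0.5) if hi.any() else True
    positive_below = bool(labels[train][~hi].mean() >= 0.5) if (~hi).any() else False
    pred_test = np.where(scores[test] >= thr, positive_above, positive_below)
    cm = ConfusionMatrix.from_predictions(pred_test, labels[test])
    return ThresholdFit(threshold=thr, positive_above=positive_above,
                        positive_below=positive_below,
                        train_size=len(train), test_size=len(test),
                        confusion=cm, metrics=metrics(cm))


# ---------------------------------------------------------------------------
# cohort I/O and plots

def cases_to_frame(cases: list[LabelledCase]) -> pd.DataFrame:
    return pd.DataFrame([{
        "case_id": c.case_id, "height_pct": c.height_pct, "zscore": c.zscore,
        "label": c.label, "completeness": c.completeness,
    } for c in cases])


def cases_from_frame(df: pd.DataFrame) -> list[LabelledCase]:
    return [LabelledCase(case_id=str(r.case_id), height_pct=float(r.height_pct),
                         zscore=float(r.zscore), label=bool(r.label),
                         completeness=float(getattr(r, "completeness", 1.0)))
            for r in df.itertuples(index=False)]


def plot_cohort(cases: list[LabelledCase], sigma1_sq: np.ndarray | None,
                out_prefix: str) -> list[str]:
    """Histogram of peak heights by class and, when eps-TNCS values are
    given, the peak-height versus modulation scatter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    df = cases_to_frame(cases)
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 100, 41)
    ax.hist(df.loc[df.label, "height_pct"], bins=bins, alpha=0.6, label="TNCS")
    ax.hist(df.loc[~df.label, "height_pct"], bins=bins, alpha=0.6, label="no TNCS")
    ax.set_xlabel("top non-origin peak height (% of origin)")
    ax.set_ylabel("cases")
    ax.legend()
    path = f"{out_prefix}_histogram.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    if sigma1_sq is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(df.height_pct, sigma1_sq, s=12,
                   c=np.where(df.label, "tab:blue", "tab:orange"))
        ax.set_xlabel("top peak height (% of origin)")
        ax.set_ylabel(r"eps-TNCS $\sigma_1^2$")
        path = f"{out_prefix}_scatter.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
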