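"""Margin classifier, cross-validated metrics, and cohort statistics.

The classifier is a soft-margin linear SVM (fixed C) trained on the
selected edge features; its unscaled decision value w.x + b is also the
"logit" the counterfactual hinge loss consumes.  Evaluation follows the
clinical convention: the patient class (label 0) is the positive class
for sensitivity/specificity unless flipped.

Cohort demographic checks mirror the usual case-control table: a Pearson
chi-square test (no continuity correction) on 2x2 sex counts and a
pooled-variance two-sample t-test reconstructed from printed age
mean/SD/n summaries.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import FeatureDataset

__all__ = [
    "MarginModel",
    "ConfusionCounts",
    "CVReport",
    "train_margin_model",
    "confusion_metrics",
    "confusion_from_predictions",
    "cross_validate_pipeline",
    "paired_ttest",
    "chi_square_2x2",
    "t_test_from_summary",
]


@dataclasses.dataclass
class MarginModel:
    """Linear maximum-margin classifier restricted to selected features."""

    weights: np.ndarray
    bias: float
    feature_ids: np.ndarray
    C: float = 1.0

    def decision_value(self, x: np.ndarray) -> np.ndarray:
        """Unscaled decision value w.x_selected + b (the hinge 'logit')."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xs = x[:, self.feature_ids] if x.shape[1] != self.weights.size else x
        return xs @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_value(x) >= 0).astype(int)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclasses.dataclass
class CVReport:
    fold_acc: np.ndarray
    fold_sen: np.ndarray
    fold_spe: np.ndarray
    fold_assignment: np.ndarray     # per-subject fold id
    selected_per_fold: list[np.ndarray]

    @property
    def mean_acc(self) -> float:
        return float(np.nanmean(self.fold_acc))

    @property
    def mean_sen(self) -> float:
        return float(np.nanmean(self.fold_sen))

    @property
    def mean_spe(self) -> float:
        return float(np.nanmean(self.fold_spe))


def train_margin_model(ds_train: FeatureDataset, mask: np.ndarray, C: float = 1.0) -> MarginModel:
    """Fit the linear SVM on the masked feature columns."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty feature mask")
    ds_train.require_both_classes()
    ids = np.flatnonzero(mask)
    clf = SVC(kernel="linear", C=C)
    clf.fit(ds_train.features[:, ids], ds_train.labels)
    return MarginModel(clf.coef_.ravel().copy(), float(clf.intercept_[0]), ids, C)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               positive_label: int = 0) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive_label
    hit = y_pred == y_true
    return ConfusionCounts(
        TP=int(np.sum(pos & hit)), FN=int(np.sum(pos & ~hit)),
        TN=int(np.sum(~pos & hit)), FP=int(np.sum(~pos & ~hit)),
    )


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, SEN, SPE); SEN or SPE is NaN when its denominator is empty."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = (counts.TP + counts.TN) / counts.total
    sen = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else float("nan")
    spe = counts.TN / (counts.TN + counts.FP) if counts.TN + counts.FP else float("nan")
    return acc, sen, spe


def cross_validate_pipeline(
    ds: FeatureDataset,
    select: Callable[[FeatureDataset, int], np.ndarray],
    seed: int,
    n_folds: int = 5,
    C: float = 1.0,
    positive_label: int = 0,
    leaky: bool = False,
) -> CVReport:
    """Nested stratified k-fold evaluation of a selection pipeline.

    ``select(ds_train, fold_seed) -> mask`` runs the entire selection stack
    on the training portion of each fold (leak-free default).  ``leaky``
    runs selection once on the full dataset before splitting — available
    only to quantify the optimistic bias of that shortcut.
    """
    counts = np.bincount(ds.labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"need at least {n_folds} subjects per class for {n_folds}-fold CV, "
            f"got {counts.tolist()}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(ds.n_subjects, dtype=int)
    accs, sens, spes, masks = [], [], [], []
    full_mask = select(ds, seed) if leaky else None
    for k, (tr, te) in enumerate(skf.split(ds.features, ds.labels)):
        assignment[te] = k
        ds_tr = ds.subset(tr)
        mask = full_mask if leaky else select(ds_tr, seed * 1000 + k)
        model = train_margin_model(ds_tr, mask, C=C)
        pred = model.predict(ds.features[te])
        acc, sen, spe = confusion_metrics(
            confusion_from_predictions(ds.labels[te], pred, positive_label))
        accs.append(acc); sens.append(sen); spes.append(spe)
        masks.append(np.flatnonzero(mask))
    return CVReport(np.array(accs), np.array(sens), np.array(spes), assignment, masks)


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Student t-test; identical vectors give (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(a == b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square independence test on a 2x2 table, df=1, no Yates."""
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), df, float(p)
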