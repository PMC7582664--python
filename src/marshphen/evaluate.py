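"""Classification evaluation: holdout, random forest, disagreement budget.

Labeled phenology-metric vectors are split 50/50 (stratified by class),
a random-forest classifier is trained on one half and scored on the other,
and the resulting confusion matrix — expressed as proportions p_ij =
share of samples classified as class i but truly class j — is decomposed
into

    OA = sum_i p_ii                                  (overall accuracy)
    QD = 1/2 sum_i |colsum_i - rowsum_i|             (quantity disagreement)
    AD = sum_i min(colsum_i - p_ii, rowsum_i - p_ii) (allocation disagreement)

with the identity OA + QD + AD = 1: quantity disagreement is the mismatch
in class marginals, allocation disagreement the remaining label swapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

#: Random-forest defaults; the classifier is supporting machinery, so the
#: field-standard ensemble size and sqrt-features split rule are used.
RF_N_ESTIMATORS = 500


@dataclass
class ConfusionProportions:
    """Square matrix p[i, j] = proportion classified as class i, truly j."""

    proportions: np.ndarray
    labels: list

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("proportions must be square")
        if np.any(p < 0):
            raise ValueError("proportions must be >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1, got {p.sum()}")
        self.proportions = p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.labels, columns=self.labels)


def holdout_split(X, y, fraction: float = 0.5, seed: int = 0):
    """Stratified-by-class holdout split at the stated fraction.

    Returns (X_train, X_test, y_train, y_test); disjoint and reproducible
    under the seed. Stratification guarantees every class appears on both
    sides, so classes with a single sample are rejected.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    singletons = labels[counts < 2]
    if len(singletons):
        raise ValueError(f"classes with a single sample cannot be split: "
                         f"{list(singletons)}")
    return train_test_split(X, y, test_size=fraction, stratify=y,
                            random_state=seed)


def classify_rf(X_train, y_train, X_test, seed: int = 0,
                n_estimators: int = RF_N_ESTIMATORS) -> np.ndarray:
    """Random-forest prediction on the test features (deterministic under
    seed). Features are the six-element phenology vectors."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError(f"feature dimensions differ: train {X_train.shape[1]}, "
                         f"test {X_test.shape[1]}")
    clf = RandomForestClassifier(n_estimators=n_estimators, max_features="sqrt",
                                 random_state=seed)
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def confusion_proportions(predicted, truth, labels=None) -> ConfusionProportions:
    """Confusion counts normalised by total n, oriented p[i, j] = predicted
    class i, true class j."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    if labels is None:
        labels = sorted(set(truth))
    extra = set(predicted) | set(truth)
    if not extra.issubset(set(labels)):
        raise ValueError(f"labels outside class set: {sorted(extra - set(labels))}")
    # sklearn orients C[i, j] = true i, predicted j; transpose.
    counts = confusion_matrix(truth, predicted, labels=labels).T
    return ConfusionProportions(proportions=counts / counts.sum(), labels=list(labels))


def quantity_disagreement(cm: ConfusionProportions) -> float:
    """QD: half the summed absolute difference between each class's true
    (column-sum) and predicted (row-sum) marginal proportions."""
    p = cm.proportions
    return float(0.5 * np.abs(p.sum(axis=0) - p.sum(axis=1)).sum())


def allocation_disagreement(cm: ConfusionProportions) -> float:
    """AD: summed per-class minimum of omission (colsum - diagonal) and
    commission (rowsum - diagonal) proportions."""
    p = cm.proportions
    d = np.diag(p)
    return float(np.minimum(p.sum(axis=0) - d, p.sum(axis=1) - d).sum())


def overall_accuracy(cm: ConfusionProportions) -> float:
    """OA: the diagonal sum (proportion correctly classified)."""
    return float(np.trace(cm.proportions))


def evaluate_classification(X, y, seed: int = 0, fraction: float = 0.5,
                            n_estimators: int = RF_N_ESTIMATORS) -> dict:
    """Full evaluation: split, classify, decompose. Returns a dict with
    oa/qd/ad, the confusion proportions and the test-set size."""
    X_train, X_test, y_train, y_test = holdout_split(X, y, fraction, seed)
    predicted = classify_rf(X_train, y_train, X_test, seed, n_estimators)
    cm = confusion_proportions(predicted, y_test, labels=sorted(set(y)))
    return {"oa": overall_accuracy(cm), "qd": quantity_disagreement(cm),
            "ad": allocation_disagreement(cm), "confusion": cm,
            "n_test": len(y_test)}
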