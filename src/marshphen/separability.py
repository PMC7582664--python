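"""Class separability in phenology-metric space.

Each vegetation class is summarised as a Gaussian in the six-dimensional
metric space (mean vector m, covariance matrix S). The Bhattacharyya
distance between classes i and j,

    B_ij = 1/8 (m_i - m_j)^T [(S_i + S_j)/2]^{-1} (m_i - m_j)
           + 1/2 ln( |(S_i + S_j)/2| / sqrt(|S_i| |S_j|) ),

combines a Mahalanobis-like mean term with a covariance-shape term. The
Jeffries-Matusita distance JMD = 2 (1 - exp(-B)) maps it into [0, 2]:
above 1.9 is excellent separability, 1.4-1.9 favorable, below 1.4 poor.
The overall JMD (OJMD) is the mean of JMD over all unordered class pairs.

No feature scaling is applied: B is invariant under any affine map applied
jointly to means and covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Interpretive JMD bands.
JMD_EXCELLENT = 1.9
JMD_FAVORABLE = 1.4

#: Relative ridge added to near-singular covariances: eps = RIDGE_REL * tr(S)/d.
#: Needed whenever a class has fewer samples than metric dimensions + 1.
RIDGE_REL = 1e-8


@dataclass
class ClassStats:
    """Per-class sample mean vector and covariance matrix in metric space."""

    class_name: str
    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        d = len(self.mean)
        if self.cov.shape != (d, d):
            raise ValueError(f"covariance shape {self.cov.shape} != ({d}, {d})")


def class_stats(vectors, class_name: str = "") -> ClassStats:
    """Sample mean and covariance (denominator n-1) of one class's vectors.

    A ridge eps*I with eps = 1e-8 tr(S)/d (floored at 1e-12) is added when
    the covariance is not positive definite, as happens for classes with
    fewer samples than dimensions + 1.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"class {class_name!r}: need >= 2 sample vectors, "
                         f"got array of shape {X.shape}")
    mean = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    d = cov.shape[0]
    eps = max(RIDGE_REL * float(np.trace(cov)) / d, 1e-12)
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < eps:  # singular or numerically indefinite
        cov = cov + (eps - min(eigmin, 0.0)) * np.eye(d)
    return ClassStats(class_name=class_name, mean=mean, cov=cov, n=X.shape[0])


def bhattacharyya(a: ClassStats, b: ClassStats) -> float:
    """Bhattacharyya distance between two Gaussian classes (>= 0)."""
    diff = a.mean - b.mean
    avg = 0.5 * (a.cov + b.cov)
    sign, logdet_avg = np.linalg.slogdet(avg)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"average covariance of pair ({a.class_name!r}, {b.class_name!r}) "
            "is not positive definite")
    mean_term = 0.125 * float(diff @ np.linalg.solve(avg, diff))
    sign_a, logdet_a = np.linalg.slogdet(a.cov)
    sign_b, logdet_b = np.linalg.slogdet(b.cov)
    if sign_a <= 0 or sign_b <= 0:
        raise np.linalg.LinAlgError(
            f"covariance of pair ({a.class_name!r}, {b.class_name!r}) "
            "is not positive definite; apply the ridge via class_stats")
    log_term = 0.5 * (logdet_avg - 0.5 * (logdet_a + logdet_b))
    return mean_term + log_term


def jmd(b: float) -> float:
    """Jeffries-Matusita distance 2 (1 - exp(-B)), in [0, 2]."""
    if b < 0:
        raise ValueError(f"Bhattacharyya distance must be >= 0, got {b}")
    return 2.0 * (1.0 - np.exp(-b))


def jmd_matrix(stats: list) -> pd.DataFrame:
    """Symmetric pairwise JMD matrix over classes (diagonal 0)."""
    names = [s.class_name for s in stats]
    n = len(stats)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jmd(bhattacharyya(stats[i], stats[j]))
    return pd.DataFrame(m, index=names, columns=names)


def ojmd(stats: list) -> float:
    """Overall JMD: mean of pairwise JMD over all unordered class pairs."""
    if len(stats) < 2:
        raise ValueError("need at least 2 classes")
    vals = [jmd(bhattacharyya(stats[i], stats[j]))
            for i in range(len(stats)) for j in range(i + 1, len(stats))]
    return float(np.mean(vals))


def separability_from_labeled(vectors, labels) -> tuple[pd.DataFrame, float]:
    """Pairwise JMD matrix and OJMD from labeled metric vectors."""
    X = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    stats = [class_stats(X[labels == c], str(c)) for c in pd.unique(labels)]
    return jmd_matrix(stats), ojmd(stats)
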