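"""Closed-form Mahalanobis metric learning (CFML).

Given labeled signatures, form the mean pair-difference scatter of
same-class pairs (M_S) and different-class pairs (M_D) and solve

    min_L  Tr(L (M_S - M_D) L^T)   s.t.  L (M_S + lambda I) L^T = I,

whose solution rows are the top-D eigenvectors of the generalized
symmetric eigenproblem  M_D v = eta (M_S + lambda I) v.  The learned
squared distance is ||L x - L y||^2, i.e. a rank-D Mahalanobis metric
M = L^T L: database signatures can be stored as D-dimensional projections
and compared with plain Euclidean distance.

The scatter matrices are computed from per-class sums (an algebraic
identity), not an O(n^2) pair loop, but define exactly the all-pairs
averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["PairScatter", "MetricModel", "build_pair_scatter", "fit_cfml",
           "learned_distance", "project"]


@dataclass
class PairScatter:
    """Mean outer products of pair differences, same-class vs different-class."""

    M_S: np.ndarray
    M_D: np.ndarray
    n_same: int
    n_diff: int


@dataclass
class MetricModel:
    """Low-rank projection L (D x F) inducing the learned squared distance."""

    L: np.ndarray
    lambda_reg: float
    eigenvalues: np.ndarray  # D generalized eigenvalues, descending

    @property
    def D(self) -> int:
        return self.L.shape[0]


def build_pair_scatter(signatures: np.ndarray, labels: np.ndarray) -> PairScatter:
    """All-pairs mean difference scatters over same- and different-label pairs.

    Uses the identity  sum_{i<j in C} (x_i-x_j)(x_i-x_j)^T
    = n_C * sum_{i in C} x_i x_i^T - s_C s_C^T  with s_C the class sum.
    """
    X = np.asarray(signatures, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("signatures must be (n, F) with one label per row")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes to define different-class pairs")
    n, F = X.shape
    G_total = X.T @ X
    s_total = X.sum(axis=0)
    sum_same = np.zeros((F, F))
    n_same = 0
    for c in classes:
        Xc = X[y == c]
        nc = Xc.shape[0]
        sc = Xc.sum(axis=0)
        sum_same += nc * (Xc.T @ Xc) - np.outer(sc, sc)
        n_same += nc * (nc - 1) // 2
    if n_same == 0:
        raise ValueError("no same-class pairs: every class is a singleton")
    sum_all = n * G_total - np.outer(s_total, s_total)
    n_all = n * (n - 1) // 2
    n_diff = n_all - n_same
    M_S = sum_same / n_same
    M_D = (sum_all - sum_same) / n_diff
    M_S = (M_S + M_S.T) / 2.0
    M_D = (M_D + M_D.T) / 2.0
    return PairScatter(M_S=M_S, M_D=M_D, n_same=n_same, n_diff=n_diff)


def fit_cfml(scatter: PairScatter, D: int, lambda_reg: float = 1.5e-4) -> MetricModel:
    """Solve the regularized CFML eigenproblem and keep the top-D directions.

    Rows of L are eigenvectors of  M_D v = eta (M_S + lambda I) v  with the
    largest eta, scaled so  L (M_S + lambda I) L^T = I, signs fixed so each
    row's largest-magnitude entry is positive.
    """
    F = scatter.M_S.shape[0]
    if not 1 <= D <= F:
        raise ValueError(f"D must be in [1, {F}], got {D}")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    B = scatter.M_S + lambda_reg * np.eye(F)
    try:
        eigvals, eigvecs = linalg.eigh(scatter.M_D, B)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "regularized same-class scatter is singular; use lambda_reg > 0"
        ) from exc
    # eigh returns ascending eigenvalues with B-orthonormal eigenvectors
    idx = np.argsort(eigvals)[::-1][:D]
    L = eigvecs[:, idx].T.copy()
    flip = np.sign(L[np.arange(D), np.abs(L).argmax(axis=1)])
    L *= flip[:, None]
    return MetricModel(L=L, lambda_reg=float(lambda_reg), eigenvalues=eigvals[idx])


def project(model: MetricModel, X: np.ndarray) -> np.ndarray:
    """Project signatures into the learned D-dimensional space (rows -> L x)."""
    return np.atleast_2d(np.asarray(X, dtype=float)) @ model.L.T


def learned_distance(model: MetricModel, x: np.ndarray, y: np.ndarray) -> float:
    """Squared Mahalanobis distance ||L x - L y||^2 under the learned metric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] != model.L.shape[1]:
        raise ValueError("x and y must be F-vectors matching the metric")
    diff = model.L @ (x - y)
    return float(diff @ diff)
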