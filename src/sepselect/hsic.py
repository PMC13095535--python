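"""Hilbert-Schmidt Independence Criterion with a Gaussian kernel.

HSIC is the squared Hilbert-Schmidt norm of the cross-covariance operator
between two variables embedded in reproducing-kernel Hilbert spaces; with a
characteristic kernel (Gaussian here) it is zero iff the variables are
independent. The package uses the standard biased empirical estimator

    HSIC_b(X, Y) = (m - 1)^{-2} tr(K H L H),   H = I - (1/m) 1 1^T,

where K and L are Gaussian Gram matrices of the two samples. During
training it penalises statistical dependence between the per-batch summary
statistics and the temporal embedding the TCN extracts, pushing the two
representations to carry complementary information.

Bandwidths follow the median heuristic (median pairwise distance, computed
per batch and treated as a constant with respect to gradients).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .autodiff import Tensor

logger = logging.getLogger(__name__)


@dataclass
class GramMatrix:
    K: np.ndarray
    sigma: float


@dataclass
class HsicValue:
    value: float
    n: int
    sigma_x: float
    sigma_y: float


def gaussian_gram(X: np.ndarray, sigma: float) -> GramMatrix:
    """Gram matrix K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D2 = squareform(pdist(X, "sqeuclidean")) if X.shape[0] > 1 else \
        np.zeros((X.shape[0], X.shape[0]))
    return GramMatrix(np.exp(-D2 / (2.0 * sigma ** 2)), float(sigma))


def median_heuristic_bandwidth(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance over distinct pairs; 1.0 if zero."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("median heuristic needs at least two points")
    med = float(np.median(pdist(X, "euclidean")))
    return med if med > 0 else 1.0


def _centering(m: int) -> np.ndarray:
    return np.eye(m) - np.full((m, m), 1.0 / m)


def hsic_empirical(X: np.ndarray, Y: np.ndarray,
                   sigma_x: float | None = None,
                   sigma_y: float | None = None) -> HsicValue:
    """Biased empirical HSIC of two aligned samples.

    Bandwidths default to the median heuristic of each sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    m = X.shape[0]
    if m < 2:
        raise ValueError("HSIC needs at least two rows")
    sx = median_heuristic_bandwidth(X) if sigma_x is None else float(sigma_x)
    sy = median_heuristic_bandwidth(Y) if sigma_y is None else float(sigma_y)
    K = gaussian_gram(X, sx).K
    L = gaussian_gram(Y, sy).K
    H = _centering(m)
    value = float(np.trace(K @ H @ L @ H)) / (m - 1) ** 2
    return HsicValue(value, m, sx, sy)


def hsic_permutation_pvalue(X: np.ndarray, Y: np.ndarray, *,
                            n_permutations: int = 99,
                            rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for the null of independence (rows of Y shuffled)."""
    rng = rng or np.random.default_rng()
    obs = hsic_empirical(X, Y).value
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = hsic_empirical(X, Y[rng.permutation(Y.shape[0])]).value
    return (1.0 + np.sum(null >= obs)) / (n_permutations + 1.0)


def hsic_loss(stat_repr: Tensor, temporal_repr: Tensor) -> Tensor:
    """Differentiable HSIC penalty between two per-batch representations.

    Bandwidths come from the median heuristic on the *current values*
    (detached, so they act as constants in the gradient). Batches of fewer
    than two rows return a zero with a warning: independence is undefined
    on a single observation.
    """
    m = stat_repr.shape[0]
    if temporal_repr.shape[0] != m:
        raise ValueError("representations must be aligned by patient")
    if m < 2:
        warnings.warn("HSIC loss undefined for batch size < 2; returning 0",
                      stacklevel=2)
        return Tensor(0.0)
    sx = median_heuristic_bandwidth(stat_repr.data)
    sy = median_heuristic_bandwidth(temporal_repr.data)
    H = Tensor(_centering(m))
    K = _gaussian_gram_t(stat_repr, sx)
    L = _gaussian_gram_t(temporal_repr, sy)
    KH = K @ H
    LH = L @ H
    # tr(KH LH) = sum((KH)^T * LH); both factors already carry the tape
    return (KH.T * LH).sum() * (1.0 / (m - 1) ** 2)


def _gaussian_gram_t(X: Tensor, sigma: float) -> Tensor:
    sq = (X * X).sum(axis=1, keepdims=True)          # (m, 1)
    d2 = sq + sq.T - 2.0 * (X @ X.T)
    d2 = d2.clip(0.0, np.inf)                        # guard tiny negatives
    return (d2 * (-1.0 / (2.0 * sigma ** 2))).exp()
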