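"""RBF similarity graphs and their symmetric normalized Laplacian.

The manifold penalty needs a graph over the training samples.  Similarity is
the radial basis function of squared Euclidean distance,

    S_ij = exp(-gamma * ||x_i - x_j||^2),

so S is symmetric with unit diagonal and entries in (0, 1].  With degree
matrix D (D_ii = sum_j S_ij) the symmetric normalized Laplacian is

    L = D^{-1/2} (D - S) D^{-1/2},

positive semi-definite with spectrum in [0, 2] and null vector D^{1/2} 1
when the graph is connected (always true here: S is strictly positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SimilarityGraph",
    "rbf_similarity",
    "normalized_laplacian",
    "median_heuristic_gamma",
]


@dataclass(frozen=True)
class SimilarityGraph:
    """Dense RBF similarity matrix with its node degrees.

    Attributes
    ----------
    S : ndarray (n, n)
        Symmetric similarity matrix, unit diagonal, entries in (0, 1].
    degrees : ndarray (n,)
        Row sums of S (the diagonal of the degree matrix D).
    gamma : float
        RBF width used to build S.
    """

    S: np.ndarray
    degrees: np.ndarray
    gamma: float

    @property
    def n(self) -> int:
        return self.S.shape[0]


def rbf_similarity(X: np.ndarray, gamma: float) -> SimilarityGraph:
    """Build the fully connected RBF similarity graph over rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 samples to build a graph, got {X.shape[0]}")
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    sq = squareform(pdist(X, metric="sqeuclidean"))
    S = np.exp(-gamma * sq)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0  # enforce exact symmetry against rounding
    return SimilarityGraph(S=S, degrees=S.sum(axis=1), gamma=float(gamma))


def normalized_laplacian(graph: SimilarityGraph) -> np.ndarray:
    """Symmetric normalized Laplacian ``D^{-1/2} (D - S) D^{-1/2}``."""
    d = graph.degrees
    if np.any(d <= 0):
        raise ValueError(
            "graph has a non-positive degree; similarity matrix is invalid "
            "(self-similarity must be 1)"
        )
    inv_sqrt = 1.0 / np.sqrt(d)
    delta = np.diag(d) - graph.S
    L = inv_sqrt[:, None] * delta * inv_sqrt[None, :]
    return (L + L.T) / 2.0


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise squared distance.

    Returns ``1 / median(||x_i - x_j||^2)`` so that a typical pair has
    similarity exp(-1); a standard kernel-width heuristic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    med = np.median(pdist(X, metric="sqeuclidean"))
    if med <= 0:
        raise ValueError("median pairwise distance is zero (duplicate rows)")
    return 1.0 / med
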