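"""K-fold cross-validation and the sequential hyperparameter search.

Out-of-fold predictions are pooled across folds and all summary statistics
(RMSE, R, R^2, Bland-Altman, folded-ECDF) are computed once on the pooled
vector, so agreement counts range over every sample exactly once.  All
training-fold state — feature standardization and the similarity graph —
is learned on the training fold only.

The hyperparameter search is sequential, not exhaustive: (1) the hidden
layer width P is scanned with long-run settings (50 iterations,
lambda1 = lambda2 = 1); (2) the iteration count is scanned at the chosen P;
(3) lambda1 and lambda2 are scanned jointly on a log2 grid from 2^-5 to 2^0
in steps of 2^0.5.  Each cell is scored by pooled k-fold RMSE; ties break
toward the smaller parameter value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import (
    BlandAltmanReport,
    EcdpSummary,
    bland_altman,
    ecdp_stats,
    pearson_r,
    r_squared,
    rmse,
)
from .solver import Hyperparameters, SLapRVFLRegressor

__all__ = [
    "CvResult",
    "kfold_cv",
    "SearchProtocol",
    "grid_search",
]


@dataclass
class CvResult:
    """Pooled out-of-fold cross-validation result."""

    fold_assignments: np.ndarray  # per-sample test-fold index
    y_true: np.ndarray
    pooled_predictions: np.ndarray
    rmse: float
    pearson_r: float
    r_squared: float
    per_fold_rmse: np.ndarray

    def bland_altman(self) -> BlandAltmanReport:
        """Agreement of pooled predictions with the reference targets."""
        return bland_altman(self.y_true, self.pooled_predictions)

    def ecdp(self) -> EcdpSummary:
        """Folded-ECDF summary of pooled prediction - reference differences."""
        return ecdp_stats(self.pooled_predictions - self.y_true)


def _fold_indices(n: int, k: int, seed: int) -> np.ndarray:
    """Shuffled fold assignment; fold sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return assignments


def kfold_cv(X, y, model_builder, k: int = 10, seed: int = 0) -> CvResult:
    """K-fold cross-validation with pooled out-of-fold predictions.

    Parameters
    ----------
    X, y : arrays
        Cohort features (n x d) and targets (n,).
    model_builder : callable
        Zero-argument factory returning a fresh unfitted regressor with
        ``fit``/``predict``.
    k : int
        Number of folds (k = n gives leave-one-out).
    seed : int
        Seed for the fold shuffle; identical seeds give identical folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    assignments = _fold_indices(n, k, seed)
    pooled = np.empty(n, dtype=float)
    per_fold = np.empty(k, dtype=float)
    for fold in range(k):
        test = assignments == fold
        train = ~test
        model = model_builder()
        model.fit(X[train], y[train])
        pred = np.asarray(model.predict(X[test]), dtype=float).ravel()
        pooled[test] = pred
        per_fold[fold] = rmse(y[test], pred)
    return CvResult(
        fold_assignments=assignments,
        y_true=y,
        pooled_predictions=pooled,
        rmse=rmse(y, pooled),
        pearson_r=pearson_r(y, pooled),
        r_squared=r_squared(y, pooled),
        per_fold_rmse=per_fold,
    )


def _default_lambda_grid() -> np.ndarray:
    # 2^-5 .. 2^0 in steps of 2^0.5: 11 values per axis
    return 2.0 ** np.arange(-5.0, 0.25, 0.5)


@dataclass
class SearchProtocol:
    """Specification of the three-stage sequential search.

    ``stage1_iter``, ``stage1_lambda`` are the long-run settings used while
    scanning P.  Shrink the grids (and k) for quick experiments; the
    defaults mirror the full protocol.
    """

    p_grid: np.ndarray = field(
        default_factory=lambda: np.arange(10, 150, 10)
    )
    iter_grid: np.ndarray = field(
        default_factory=lambda: np.arange(1, 101)
    )
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    stage1_iter: int = 50
    stage1_lambda: float = 1.0
    k: int = 10
    base: Hyperparameters = field(default_factory=Hyperparameters)


def _score(X, y, hyper: Hyperparameters, k: int, seed: int) -> float:
    builder = lambda: SLapRVFLRegressor(hyper=hyper)
    return kfold_cv(X, y, builder, k=k, seed=seed).rmse


def grid_search(X, y, protocol: SearchProtocol | None = None, seed: int = 0):
    """Sequential search for P, iteration count and (lambda1, lambda2).

    Returns ``(best, trace)`` where ``best`` is the selected
    :class:`Hyperparameters` and ``trace`` is a list of
    ``{"stage", "params", "rmse"}`` records, one per evaluated cell.
    Within each stage the first minimizer in scan order wins, so ties break
    toward the smaller parameter value.
    """
    protocol = protocol or SearchProtocol()
    for name in ("p_grid", "iter_grid", "lambda_grid"):
        if len(getattr(protocol, name)) == 0:
            raise ValueError(f"{name} must be non-empty")
    trace = []

    def scan(stage, cells, make_hyper):
        best_cell, best_score = None, np.inf
        for cell in cells:
            score = _score(X, y, make_hyper(cell), protocol.k, seed)
            trace.append({"stage": stage, "params": cell, "rmse": score})
            if score < best_score:  # strict: ties keep the earlier cell
                best_cell, best_score = cell, score
        return best_cell

    base = protocol.base
    s1 = base.replace(
        max_iter=protocol.stage1_iter,
        lambda1=protocol.stage1_lambda,
        lambda2=protocol.stage1_lambda,
    )
    best_p = scan("P", [int(p) for p in protocol.p_grid],
                  lambda p: s1.replace(P=p))

    s2 = s1.replace(P=best_p)
    best_iter = scan("max_iter", [int(t) for t in protocol.iter_grid],
                     lambda t: s2.replace(max_iter=t))

    s3 = base.replace(P=best_p, max_iter=best_iter)
    cells = [
        (float(l1), float(l2))
        for l1 in protocol.lambda_grid
        for l2 in protocol.lambda_grid
    ]
    best_l1, best_l2 = scan("lambda", cells,
                            lambda c: s3.replace(lambda1=c[0], lambda2=c[1]))

    best = s3.replace(lambda1=best_l1, lambda2=best_l2)
    return best, trace
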