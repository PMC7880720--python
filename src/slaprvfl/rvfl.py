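"""Baseline random vector functional link (RVFL) regression.

An RVFL network is a single-hidden-layer network whose hidden weights and
biases are drawn at random once and never trained.  The output layer sees
both the raw inputs (direct links) and the hidden activations, so the design
matrix is the column concatenation ``H = [H1 H2]`` with ``H1 = X`` and
``H2[i, j] = g(a_j · x_i + b_j)``.  Only the output weights ``beta`` are
fitted, by ridge-regularized least squares in closed form:

    beta = (H'H + lambda * I)^{-1} H'Y

The default activation is the Gaussian bump ``g(u) = exp(-u^2)``, whose
outputs lie in ``(0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "HiddenParams",
    "DesignMatrix",
    "init_hidden_params",
    "gaussian_activation",
    "build_design_matrix",
    "ridge_solve",
    "RVFLRegressor",
    "StandardizationStats",
    "fit_standardization",
    "apply_standardization",
]


def gaussian_activation(u):
    """Gaussian activation ``g(u) = exp(-u**2)``, applied elementwise."""
    u = np.asarray(u, dtype=float)
    return np.exp(-np.square(u))


_ACTIVATIONS = {
    "gaussian": gaussian_activation,
}


@dataclass(frozen=True)
class HiddenParams:
    """Fixed random hidden-layer parameters of an RVFL network.

    Attributes
    ----------
    a : ndarray of shape (P, d)
        Hidden input weights; row ``j`` holds the weights of hidden node ``j``.
    b : ndarray of shape (P,)
        Hidden biases.
    activation : str
        Name of the scalar activation ("gaussian").
    seed : int
        Seed used to draw ``a`` and ``b``; regenerating with the same
        ``(d, P, seed)`` reproduces them bit-for-bit.
    """

    a: np.ndarray
    b: np.ndarray
    activation: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.a.ndim != 2 or self.b.ndim != 1:
            raise ValueError("a must be 2-D (P, d) and b 1-D (P,)")
        if self.a.shape[0] != self.b.shape[0]:
            raise ValueError(
                f"inconsistent hidden sizes: a has {self.a.shape[0]} rows, "
                f"b has length {self.b.shape[0]}"
            )
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def n_hidden(self) -> int:
        return self.a.shape[0]

    @property
    def n_features(self) -> int:
        return self.a.shape[1]

    def activate(self, u):
        return _ACTIVATIONS[self.activation](u)


def init_hidden_params(
    d: int, P: int, seed: int = 0, activation: str = "gaussian"
) -> HiddenParams:
    """Draw the fixed hidden weights and biases of an RVFL network.

    Entries of ``a`` (P x d) and ``b`` (P,) are i.i.d. uniform on [-1, 1],
    the common RVFL convention: bounded draws keep pre-activations of
    standardized inputs in a range where the Gaussian bump is informative.

    Parameters
    ----------
    d : int
        Input dimension (>= 1).
    P : int
        Number of hidden nodes (>= 1).
    seed : int
        Seed for the random generator; identical arguments give identical
        parameters.
    """
    if d < 1:
        raise ValueError(f"input dimension d must be >= 1, got {d}")
    if P < 1:
        raise ValueError(f"hidden node count P must be >= 1, got {P}")
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1.0, 1.0, size=(P, d))
    b = rng.uniform(-1.0, 1.0, size=P)
    return HiddenParams(a=a, b=b, activation=activation, seed=seed)


@dataclass(frozen=True)
class DesignMatrix:
    """The concatenated RVFL design matrix ``H = [H1 H2]`` (n x (d+P))."""

    H: np.ndarray
    n: int
    d: int
    P: int


def build_design_matrix(
    X: np.ndarray, hidden: HiddenParams, include_bias: bool = False
) -> DesignMatrix:
    """Build ``H = [H1 H2]`` with ``H1 = X`` and Gaussian hidden activations.

    ``H2[i, j] = g(a_j . x_i + b_j)``.  With ``include_bias`` a constant ones
    column is appended to the direct-link block (off by default: the plain
    formulation has no intercept column).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != hidden.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns but hidden params expect "
            f"{hidden.n_features}"
        )
    pre = X @ hidden.a.T + hidden.b  # (n, P)
    H2 = hidden.activate(pre)
    blocks = [X]
    if include_bias:
        blocks.append(np.ones((X.shape[0], 1)))
    blocks.append(H2)
    H = np.concatenate(blocks, axis=1)
    d_direct = X.shape[1] + (1 if include_bias else 0)
    return DesignMatrix(H=H, n=X.shape[0], d=d_direct, P=hidden.n_hidden)


def _solve_spd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric A; Cholesky first, generic fallback."""
    try:
        return scipy.linalg.solve(A, B, assume_a="pos")
    except np.linalg.LinAlgError:
        try:
            return scipy.linalg.solve(A, B, assume_a="sym")
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
            raise np.linalg.LinAlgError(
                "normal-equation system is singular; increase the ridge "
                "penalty (lambda) to make it positive definite"
            ) from exc


def ridge_solve(H, Y, lambda_ridge: float) -> np.ndarray:
    """Closed-form ridge output weights ``(H'H + lambda I)^{-1} H'Y``.

    Uses a symmetric positive-definite linear solve, never an explicit
    inverse.  ``lambda_ridge = 0`` is allowed only when ``H'H`` is
    nonsingular; a singular system raises a descriptive error.
    """
    if isinstance(H, DesignMatrix):
        H = H.H
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if H.shape[0] != Y.shape[0]:
        raise ValueError(
            f"H has {H.shape[0]} rows but Y has {Y.shape[0]}"
        )
    if lambda_ridge < 0:
        raise ValueError(f"lambda_ridge must be >= 0, got {lambda_ridge}")
    A = H.T @ H
    A[np.diag_indices_from(A)] += lambda_ridge
    rhs = H.T @ Y
    beta = _solve_spd(A, rhs)
    resid = np.linalg.norm(A @ beta - rhs)
    scale = np.linalg.norm(rhs)
    if scale > 0 and resid > 1e-6 * scale:
        raise np.linalg.LinAlgError(
            "ridge system solved inaccurately (residual "
            f"{resid:.3e} vs scale {scale:.3e}); the system is numerically "
            "singular — use lambda_ridge > 0"
        )
    return beta


@dataclass
class StandardizationStats:
    """Per-feature z-score statistics learned on the training fold."""

    means: np.ndarray
    sds: np.ndarray


def fit_standardization(X: np.ndarray) -> StandardizationStats:
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)  # constant columns pass through
    return StandardizationStats(means=means, sds=sds)


def apply_standardization(X: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    return (np.asarray(X, dtype=float) - stats.means) / stats.sds


@dataclass
class RVFLRegressor:
    """Baseline ridge-trained RVFL regressor.

    Parameters
    ----------
    P : int
        Number of hidden nodes.
    lambda_ridge : float
        Ridge coefficient of the closed-form output-weight solve.
    seed : int
        Seed for the random hidden parameters.
    include_bias : bool
        Append a ones column to the direct-link block.
    standardize : bool
        z-score features with training statistics (recommended: random
        projections and the Gaussian bump are scale sensitive).
    center_target : bool
        Fit on ``y - mean(y)`` and add the training mean back at predict.
        The design matrix has no intercept column, so without centering the
        column span must absorb the target's location — which it cannot for
        targets far from zero (e.g. body weights).
    """

    P: int = 100
    lambda_ridge: float = 1.0
    seed: int = 0
    include_bias: bool = False
    standardize: bool = True
    center_target: bool = True

    beta_: np.ndarray = field(default=None, repr=False)
    hidden_: HiddenParams = field(default=None, repr=False)
    scaler_: StandardizationStats = field(default=None, repr=False)
    y_mean_: np.ndarray = field(default=None, repr=False)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        self.y_mean_ = y.mean(axis=0) if self.center_target else np.zeros(y.shape[1])
        self.scaler_ = fit_standardization(X)
        Z = apply_standardization(X, self.scaler_) if self.standardize else X
        self.hidden_ = init_hidden_params(X.shape[1], self.P, self.seed)
        design = build_design_matrix(Z, self.hidden_, self.include_bias)
        self.beta_ = ridge_solve(design.H, y - self.y_mean_, self.lambda_ridge)
        return self

    def predict(self, X):
        if self.beta_ is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.hidden_.n_features:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects "
                f"{self.hidden_.n_features}"
            )
        Z = apply_standardization(X, self.scaler_) if self.standardize else X
        design = build_design_matrix(Z, self.hidden_, self.include_bias)
        pred = design.H @ self.beta_ + self.y_mean_
        return pred[:, 0] if pred.shape[1] == 1 else pred
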