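"""Synthetic hemodialysis-style cohorts and sparse-linear fixtures.

No public dry-weight cohort exists, so testing and benchmarking run on
synthetic cohorts that reproduce the published marginal structure of a
476-patient hemodialysis data set: per-feature means and SDs, a binary
gender feature with a 312/164 male/female split, and each feature's Pearson
correlation with the dry-weight target (BMI dominant at r ~ 0.956).

Generation model: a single standard-normal latent factor f carries the
target signal.  The target is

    y = target_mean + sqrt(target_sd^2 - noise_sd^2) * f + N(0, noise_sd^2),

and each feature loads on f with a loading chosen so its population
correlation with y equals the requested value (binary features through a
thresholded latent normal, with the point-biserial attenuation factor
divided out).  Matching every marginal feature-target correlation is
impossible with mutually independent features here, because the requested
squared correlations sum above 1; the shared factor resolves that and
induces feature-feature correlations r_i * r_j as a side effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "realized_summary",
    "generate_sparse_linear",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One cohort feature: marginal distribution + target correlation.

    Continuous features are normal(mean, sd); binary features are 0/1 with
    ``P(x = 1) = proportion`` (mean/sd are ignored).  ``target_corr`` is the
    requested Pearson correlation with the target.
    """

    name: str
    target_corr: float
    mean: float = 0.0
    sd: float = 1.0
    kind: str = "continuous"  # "continuous" | "binary"
    proportion: float = 0.5

    def __post_init__(self):
        if not -1.0 < self.target_corr < 1.0:
            raise ValueError(
                f"{self.name}: |target_corr| must be < 1, got {self.target_corr}"
            )
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "binary" and not 0.0 < self.proportion < 1.0:
            raise ValueError(f"{self.name}: proportion must be in (0, 1)")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort: features, target location and noise."""

    features: tuple
    n: int = 476
    target_mean: float = 60.0  # kg, plausible dry-weight location
    target_sd: float = 10.0  # kg
    noise_sd: float = 2.0  # kg of target variance unexplained by features
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 <= self.noise_sd < self.target_sd:
            raise ValueError("need 0 <= noise_sd < target_sd")

    def replace(self, **changes) -> "CohortSpec":
        d = asdict(self)
        d["features"] = self.features
        d.update(changes)
        return CohortSpec(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = [asdict(f) for f in self.features]
        return d


def default_cohort_spec(n: int = 476, seed: int = 0, **changes) -> CohortSpec:
    """The hemodialysis-cohort recipe used throughout the package.

    Feature order: age, gender (male=1), SBP, DBP, BMI, HR, years of
    dialysis.  Marginals and feature-target correlations follow the
    published cohort summary; target mean/SD (60 +/- 10 kg) and noise SD
    (2 kg) are the package's own plausible defaults since no dry-weight
    summary statistics were published.
    """
    features = (
        FeatureSpec("age", -0.2341, mean=54.17, sd=14.22),
        FeatureSpec("gender", -0.4489, kind="binary", proportion=312 / 476),
        FeatureSpec("sbp", -0.1739, mean=150.64, sd=29.36),
        FeatureSpec("dbp", -0.1249, mean=88.32, sd=19.56),
        FeatureSpec("bmi", 0.9558, mean=22.96, sd=2.95),
        FeatureSpec("hr", 0.1862, mean=73.41, sd=8.92),
        FeatureSpec("yd", -0.1069, mean=5.97, sd=3.22),
    )
    return CohortSpec(features=features, n=n, seed=seed, **changes)


def _point_biserial_attenuation(p: float) -> float:
    """Correlation ratio between a thresholded 0/1 variable and its latent.

    For x = 1{z > c} with z standard normal and P(x=1) = p, the
    point-biserial correlation of x with any variable jointly normal with z
    equals this factor times the latent correlation.
    """
    c = stats.norm.ppf(1.0 - p)
    return stats.norm.pdf(c) / np.sqrt(p * (1.0 - p))


def _latent_loadings(spec: CohortSpec) -> np.ndarray:
    """Per-feature loading on the latent target factor.

    Chosen so that corr(feature, y) equals each requested target_corr given
    the explained fraction of target variance; raises when a requested
    correlation is unreachable (loading would exceed 1 in magnitude).
    """
    signal_frac = np.sqrt(1.0 - (spec.noise_sd / spec.target_sd) ** 2)
    loadings = np.empty(len(spec.features))
    for j, f in enumerate(spec.features):
        rho = f.target_corr / signal_frac
        if f.kind == "binary":
            rho /= _point_biserial_attenuation(f.proportion)
        if not -1.0 < rho < 1.0:
            raise ValueError(
                f"infeasible correlation structure: feature {f.name!r} needs "
                f"a latent loading of {rho:.3f} (|loading| must be < 1); "
                "reduce noise_sd or the requested target_corr"
            )
        loadings[j] = rho
    return loadings


def generate_cohort(spec: CohortSpec):
    """Draw a cohort ``(X, y)`` from the latent-factor recipe.

    Returns ``X`` of shape (n, d) in the spec's feature order and ``y`` of
    shape (n,) in target units.  Output is a pure function of the spec
    (bit-reproducible per seed).
    """
    loadings = _latent_loadings(spec)
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n, len(spec.features)
    f_lat = rng.standard_normal(n)
    X = np.empty((n, d))
    for j, (f, rho) in enumerate(zip(spec.features, loadings)):
        z = rho * f_lat + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        if f.kind == "binary":
            X[:, j] = (z > stats.norm.ppf(1.0 - f.proportion)).astype(float)
        else:
            X[:, j] = f.mean + f.sd * z
    signal_sd = np.sqrt(spec.target_sd**2 - spec.noise_sd**2)
    y = (
        spec.target_mean
        + signal_sd * f_lat
        + spec.noise_sd * rng.standard_normal(n)
    )
    return X, y


def realized_summary(X, y, spec: CohortSpec) -> list:
    """Realized per-feature mean/SD (or proportion) and target correlation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    out = []
    for j, f in enumerate(spec.features):
        col = X[:, j]
        row = {
            "name": f.name,
            "kind": f.kind,
            "target_corr": float(stats.pearsonr(col, y).statistic),
            "spec_target_corr": f.target_corr,
        }
        if f.kind == "binary":
            row["proportion"] = float(col.mean())
            row["spec_proportion"] = f.proportion
        else:
            row["mean"] = float(col.mean())
            row["sd"] = float(col.std(ddof=1))
            row["spec_mean"] = f.mean
            row["spec_sd"] = f.sd
        out.append(row)
    return out


def generate_sparse_linear(
    n: int, d: int, n_active: int, noise_sd: float = 0.1, seed: int = 0
):
    """Sparse linear fixture for row-sparsity recovery experiments.

    ``X`` is standard normal (n, d); the true coefficient vector is nonzero
    on a random support of size ``n_active`` with magnitudes uniform in
    [0.5, 1.5] and random signs; ``y = X w + noise``.  Returns
    ``(X, y, true_support)`` with the support sorted ascending.
    """
    if not 1 <= n_active <= d:
        raise ValueError(f"need 1 <= n_active <= d, got n_active={n_active}, d={d}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    support = np.sort(rng.choice(d, size=n_active, replace=False))
    w = np.zeros(d)
    w[support] = rng.uniform(0.5, 1.5, size=n_active) * rng.choice(
        [-1.0, 1.0], size=n_active
    )
    y = X @ w + noise_sd * rng.standard_normal(n)
    return X, y, support
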