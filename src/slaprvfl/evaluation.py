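"""Regression metrics and method-agreement statistics.

Covers the evaluation toolkit used for dry-weight prediction studies:
RMSE, Pearson correlation, coefficient of determination, Bland-Altman
agreement analysis, and folded empirical-CDF ("mountain plot") summaries of
the difference distribution.

Sign convention: differences are ``predicted - reference`` throughout, so a
negative mean difference reads as underestimation of the reference method.

Note on R vs R-squared: ``r_squared`` is the coefficient of determination
1 - SS_res/SS_tot, which is not the square of the Pearson correlation when
the predictions are bias- or scale-shifted; both are reported because
method-comparison tables commonly print both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "rmse",
    "pearson_r",
    "r_squared",
    "BlandAltmanReport",
    "agreement_limits",
    "bland_altman",
    "EcdpSummary",
    "ecdp_stats",
]


def _as_vector(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return v


def rmse(y_true, y_pred) -> float:
    """Root mean square error ``sqrt(mean((y_true - y_pred)^2))``."""
    y_true = _as_vector(y_true, "y_true")
    y_pred = _as_vector(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pearson_r(y_true, y_pred) -> float:
    """Sample Pearson correlation coefficient."""
    y_true = _as_vector(y_true, "y_true")
    y_pred = _as_vector(y_pred, "y_pred")
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(y_true, y_pred).statistic)


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y_true = _as_vector(y_true, "y_true")
    y_pred = _as_vector(y_pred, "y_pred")
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class BlandAltmanReport:
    """Agreement statistics between a candidate method and a reference.

    All quantities are in the units of the measurements (kg for dry weight).
    ``loa_lower``/``loa_upper`` are the 95% limits of agreement
    mean +/- 1.96 SD; ``ci_mean`` is the Student-t 95% confidence interval
    of the mean difference.  About 95% of differences are expected inside
    the limits when differences are roughly normal; a method is commonly
    called clinically acceptable when >= 95% of points fall inside.
    """

    n: int
    mean_diff: float
    sd_diff: float
    ci_mean: tuple
    loa_lower: float
    loa_upper: float
    n_outside: int

    @property
    def ratio_outside(self) -> float:
        return self.n_outside / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "ci_mean_lower": self.ci_mean[0],
            "ci_mean_upper": self.ci_mean[1],
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "n_outside": self.n_outside,
            "ratio_outside": self.ratio_outside,
        }


def agreement_limits(mean_diff: float, sd_diff: float, n: int):
    """Limits of agreement and t-based CI of the mean from summary stats.

    Returns ``(loa_lower, loa_upper, ci_lower, ci_upper)``.  Useful for
    reconstructing published agreement tables from their printed mean/SD/n.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    half = 1.96 * sd_diff
    t_crit = stats.t.ppf(0.975, df=n - 1)
    ci_half = t_crit * sd_diff / np.sqrt(n)
    return (
        mean_diff - half,
        mean_diff + half,
        mean_diff - ci_half,
        mean_diff + ci_half,
    )


def bland_altman(reference, measured) -> BlandAltmanReport:
    """Bland-Altman agreement analysis of ``measured`` against ``reference``.

    Differences are ``measured - reference``; SD uses the n-1 denominator;
    differences strictly outside the limits of agreement are counted.
    """
    reference = _as_vector(reference, "reference")
    measured = _as_vector(measured, "measured")
    if reference.shape != measured.shape:
        raise ValueError("reference and measured must have equal length")
    n = reference.size
    if n < 3:
        raise ValueError(f"Bland-Altman analysis needs n >= 3, got {n}")
    diffs = measured - reference
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_lower, loa_upper, ci_lo, ci_hi = agreement_limits(mean, sd, n)
    outside = int(np.sum((diffs < loa_lower) | (diffs > loa_upper)))
    return BlandAltmanReport(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        ci_mean=(ci_lo, ci_hi),
        loa_lower=loa_lower,
        loa_upper=loa_upper,
        n_outside=outside,
    )


@dataclass(frozen=True)
class EcdpSummary:
    """Folded empirical-CDF ("mountain plot") summary of differences.

    ``folded_curve`` holds ``(difference, min(F, 1-F))`` pairs over the
    sorted differences; the folded fraction lies in [0, 0.5] and peaks at
    the median, so narrow mountains mean tight agreement.
    """

    highest: float
    lowest: float
    median: float
    folded_curve: np.ndarray  # (n, 2): sorted value, folded fraction

    def to_dict(self) -> dict:
        return {
            "highest": self.highest,
            "lowest": self.lowest,
            "median": self.median,
        }


def ecdp_stats(differences) -> EcdpSummary:
    """Order statistics and folded empirical CDF of a difference sample."""
    d = _as_vector(differences, "differences")
    srt = np.sort(d)
    n = srt.size
    F = np.arange(1, n + 1) / n
    folded = np.minimum(F, 1.0 - F)  # fold the ECDF at 1/2
    curve = np.column_stack([srt, folded])
    return EcdpSummary(
        highest=float(srt[-1]),
        lowest=float(srt[0]),
        median=float(np.median(d)),
        folded_curve=curve,
    )
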