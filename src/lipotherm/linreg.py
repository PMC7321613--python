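"""Simple linear regression with the full diagnostic set used by every fitting stage.

Every model in the package (retention vs. modifier fraction, ln k vs. 1/T,
ln alpha vs. 1/T, cross-system comparisons) reduces to ordinary least squares
on two vectors, so slope, intercept, R^2, F, residual standard error and 95%
confidence half-widths are computed once here and carried everywhere as a
:class:`LinearFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DegenerateDesignError, InsufficientDataError

__all__ = ["LinearFit", "fit_ols"]


@dataclass(frozen=True)
class LinearFit:
    """Result of a simple OLS fit y = slope * x + intercept.

    Attributes
    ----------
    slope, intercept
        Least-squares estimates.
    n
        Number of points (>= 3).
    r2
        Coefficient of determination, equal to the squared Pearson
        correlation of x and y for simple regression.
    f_stat
        F statistic for the slope, computed as (n - 2) * r2 / (1 - r2);
        infinite for an exact line.
    s_e
        Residual standard error, sqrt(SS_res / (n - 2)).
    se_slope, se_intercept
        Standard errors of the estimates.
    ci95_slope, ci95_intercept
        Symmetric 95% confidence half-widths (Student t, n - 2 df).
    residuals
        Per-point residuals y - (slope * x + intercept); sum to zero.
    """

    slope: float
    intercept: float
    n: int
    r2: float
    f_stat: float
    s_e: float
    se_slope: float
    se_intercept: float
    ci95_slope: float
    ci95_intercept: float
    residuals: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        """JSON-ready summary (residuals excluded)."""
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "r2": self.r2,
            "f_stat": self.f_stat,
            "s_e": self.s_e,
            "se_slope": self.se_slope,
            "se_intercept": self.se_intercept,
            "ci95_slope": self.ci95_slope,
            "ci95_intercept": self.ci95_intercept,
        }

    def summary(self) -> str:
        return (
            f"y = {self.slope:.6g}(±{self.ci95_slope:.4g}) x "
            f"+ {self.intercept:.6g}(±{self.ci95_intercept:.4g})\n"
            f"n = {self.n}, R^2 = {self.r2:.4f}, F = {self.f_stat:.4f}, "
            f"s_e = {self.s_e:.6g}"
        )


def fit_ols(x, y) -> LinearFit:
    """Fit y on x by ordinary least squares with closed-form diagnostics.

    The "±" half-widths are 95% confidence limits from the Student t
    distribution with n - 2 degrees of freedom.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 points, or lengths differ.
    DegenerateDesignError
        If x is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InsufficientDataError(
            f"x and y must be equal-length 1-d series, got {x.shape} and {y.shape}"
        )
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 points for OLS, got {n}")
    if np.all(x == x[0]):
        raise DegenerateDesignError("x is constant; slope is unidentifiable")

    res = stats.linregress(x, y)
    slope = float(res.slope)
    intercept = float(res.intercept)
    residuals = y - (slope * x + intercept)
    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    # r2 via explained fraction; guard the flat-y case (ss_tot == 0 -> exact fit).
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
    df = n - 2
    s_e = float(np.sqrt(ss_res / df))
    f_stat = float("inf") if r2 >= 1.0 else df * r2 / (1.0 - r2)
    tq = float(stats.t.ppf(0.975, df))
    se_slope = float(res.stderr)
    se_intercept = float(res.intercept_stderr)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        n=n,
        r2=r2,
        f_stat=f_stat,
        s_e=s_e,
        se_slope=se_slope,
        se_intercept=se_intercept,
        ci95_slope=tq * se_slope,
        ci95_intercept=tq * se_intercept,
        residuals=residuals,
    )
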