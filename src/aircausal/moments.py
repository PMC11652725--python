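"""First and second moments of a variable set, with moment-based OLS.

Both finite cohorts and the generator's exact implied distribution reduce to
a (mean vector, covariance matrix, n) triple, so every linear fit in the
package runs through the same code path: ordinary least squares computed from
the moments. On a sample this is algebraically identical to OLS on the raw
data; on the implied population moments it yields the exact path
coefficients, which is what makes population-level identities (total =
direct + indirect) testable to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError


@dataclass
class Moments:
    """Mean vector and covariance matrix over named variables.

    ``n`` is the number of observations behind a sample estimate, or ``None``
    for exact population moments.
    """

    mean: pd.Series
    cov: pd.DataFrame
    n: int | None = None

    def __post_init__(self):
        if list(self.mean.index) != list(self.cov.index) or list(self.cov.index) != list(
            self.cov.columns
        ):
            raise ValueError("mean/cov indices must agree")

    @property
    def variables(self) -> list[str]:
        return list(self.mean.index)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, columns=None) -> "Moments":
        cols = list(columns) if columns is not None else list(df.columns)
        sub = df[cols].astype(float)
        if len(sub) < 2:
            raise DegenerateDataError("need at least 2 rows to form moments")
        return cls(mean=sub.mean(), cov=sub.cov(), n=len(sub))


@dataclass
class LinearFit:
    """OLS fit of ``y`` on ``xs`` derived from second moments."""

    y: str
    xs: tuple[str, ...]
    coef: dict[str, float]
    intercept: float
    resid_sd: float
    n: int | None


def regress(moments: Moments, y: str, xs) -> LinearFit:
    """Ordinary least squares of ``y`` on ``xs`` from the moments.

    Raises :class:`DegenerateDataError` on a singular regressor covariance
    (collinear predictors), naming the set.
    """
    xs = tuple(xs)
    if not xs:
        var_y = float(moments.cov.loc[y, y])
        return LinearFit(y, xs, {}, float(moments.mean[y]), float(np.sqrt(max(var_y, 0.0))), moments.n)
    sxx = moments.cov.loc[list(xs), list(xs)].to_numpy()
    sxy = moments.cov.loc[list(xs), y].to_numpy()
    try:
        beta = np.linalg.solve(sxx, sxy)
    except np.linalg.LinAlgError:
        raise DegenerateDataError(f"singular regressor covariance for {xs}") from None
    # guard against a numerically near-singular solve
    if not np.all(np.isfinite(beta)) or np.linalg.cond(sxx) > 1e12:
        raise DegenerateDataError(f"collinear regressors {xs} for outcome {y!r}")
    intercept = float(moments.mean[y] - beta @ moments.mean[list(xs)].to_numpy())
    resid_var = float(moments.cov.loc[y, y] - beta @ sxy)
    resid_sd = float(np.sqrt(max(resid_var, 0.0)))
    return LinearFit(y, xs, dict(zip(xs, map(float, beta))), intercept, resid_sd, moments.n)
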