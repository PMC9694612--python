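"""Per-response goodness-of-fit statistics and residual diagnostics.

For observed values x_exp and model predictions x_pre (length N, with n
fitted constants):

    chi2 = Σ (x_exp − x_pre)² / (N − n)          reduced chi-square
    rmse = sqrt( Σ (x_pre − x_exp)² / N )        root mean square error
    mbe  = mean(x_pre − x_exp)                   mean bias error
    mpe  = 100 · mean(|x_pre − x_exp| / x_exp)   mean (absolute) percentage error

plus the squared Pearson correlation r², and the bias-adjusted sample
skewness and excess kurtosis, mean, standard deviation and variance of the
residuals (x_pre − x_exp).  By construction chi2 = rmse²·N/(N−n) and the
residual mean equals the MBE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FitRow", "goodness_of_fit", "fit_table", "write_fit_table"]

#: CSV column order for the fit-table export.
FIT_COLUMNS = ("chi2", "rmse", "mbe", "mpe", "r2", "skew", "kurt", "mean", "stdev", "var")


@dataclass
class FitRow:
    """One response's goodness-of-fit record."""

    chi2: float
    rmse: float
    mbe: float
    mpe: float
    r2: float
    skewness: float
    kurtosis: float
    residual_mean: float
    residual_stdev: float
    residual_variance: float
    n_obs: int
    n_const: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "chi2": self.chi2,
                "rmse": self.rmse,
                "mbe": self.mbe,
                "mpe": self.mpe,
                "r2": self.r2,
                "skew": self.skewness,
                "kurt": self.kurtosis,
                "mean": self.residual_mean,
                "stdev": self.residual_stdev,
                "var": self.residual_variance,
            }
        )


def goodness_of_fit(x_exp, x_pre, n_const: int = 1) -> FitRow:
    """Compute the full fit-statistics row for one response.

    Parameters
    ----------
    x_exp, x_pre
        Observed and predicted values, equal length N ≥ 2.
    n_const
        Number of model constants n in the reduced chi-square denominator
        N − n.  Defaults to 1; when n ≥ N the chi-square is reported as NaN.

    Notes
    -----
    MPE uses the absolute relative error; observations equal to zero make it
    undefined, in which case NaN is reported with a warning.  r² is NaN when
    either vector has zero variance.
    """
    x_exp = np.asarray(x_exp, dtype=float)
    x_pre = np.asarray(x_pre, dtype=float)
    if x_exp.shape != x_pre.shape or x_exp.ndim != 1:
        raise ValueError(f"shape mismatch: {x_exp.shape} vs {x_pre.shape}")
    n = len(x_exp)
    if n < 2:
        raise ValueError("need at least 2 observations")

    d = x_pre - x_exp
    sse = float(np.sum(d**2))
    rmse = math.sqrt(sse / n)
    mbe = float(np.mean(d))

    if n_const >= n:
        chi2 = float("nan")
    else:
        chi2 = sse / (n - n_const)

    if np.any(x_exp == 0):
        warnings.warn(
            "MPE undefined: at least one observed value is zero", RuntimeWarning
        )
        mpe = float("nan")
    else:
        mpe = 100.0 * float(np.mean(np.abs(d / x_exp)))

    if np.std(x_exp) == 0 or np.std(x_pre) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(x_exp, x_pre)[0, 1] ** 2)

    if np.std(d) == 0 or n < 4:
        # degenerate or too short for bias-adjusted higher moments
        skew, kurt = float("nan"), float("nan")
        if n >= 3 and np.std(d) > 0:
            skew = float(stats.skew(d, bias=False))
    else:
        skew = float(stats.skew(d, bias=False))
        kurt = float(stats.kurtosis(d, fisher=True, bias=False))

    return FitRow(
        chi2=chi2,
        rmse=rmse,
        mbe=mbe,
        mpe=mpe,
        r2=r2,
        skewness=skew,
        kurtosis=kurt,
        residual_mean=mbe,
        residual_stdev=float(np.std(d, ddof=1)),
        residual_variance=float(np.var(d, ddof=1)),
        n_obs=n,
        n_const=n_const,
    )


def fit_table(
    Y_exp: np.ndarray,
    Y_pre: np.ndarray,
    names: list[str],
    n_const: int = 1,
) -> pd.DataFrame:
    """Fit-statistics rows for a block of responses (columns of Y)."""
    Y_exp = np.atleast_2d(np.asarray(Y_exp, dtype=float))
    Y_pre = np.atleast_2d(np.asarray(Y_pre, dtype=float))
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(names):
            rows[name] = goodness_of_fit(Y_exp[:, j], Y_pre[:, j], n_const).as_series()
    out = pd.DataFrame(rows).T
    out.index.name = "response"
    return out[list(FIT_COLUMNS)]


def write_fit_table(table: pd.DataFrame, path) -> None:
    """Export a fit table as CSV with the canonical column header."""
    table.to_csv(path, float_format="%.17g", encoding="utf-8")
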