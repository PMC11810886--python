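"""Descriptive statistics, gradient verification and the yield regression.

Phase-I/II bookkeeping around the inductive method: per-strip summaries of
soil tests, yield and uptake; a check that strip means actually form a
fertility gradient (the method's premise); and the corroborating
multiple-regression of yield on uptake, soil tests, doses and manure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .schema import YIELD_MODEL_PREDICTORS

DEFAULT_SUMMARY_VARIABLES = (
    "s_n", "s_p", "s_k", "yield_kg_ha", "u_n", "u_p", "u_k",
)


class CollinearPredictorError(ValueError):
    """The regression design is rank deficient; names the offending column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"rank-deficient design: collinear column {column!r}")


def summarize_strips(
    plots: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_SUMMARY_VARIABLES,
) -> pd.DataFrame:
    """Per-strip, per-variable descriptive statistics.

    Returns one row per (strip, variable) with n, min, max, mean, sample SD
    (n-1 denominator), CV% = 100*SD/mean and median.  With a single
    observation SD and CV are reported as undefined (NaN) and flagged via
    ``sd_defined = False`` rather than as zero.
    """
    missing = [v for v in variables if v not in plots.columns]
    if missing:
        raise KeyError(f"missing variable(s): {', '.join(missing)}")
    rows = []
    for strip, grp in plots.groupby("strip", sort=True):
        for var in variables:
            x = grp[var].to_numpy(dtype=float)
            n = len(x)
            sd = float(np.std(x, ddof=1)) if n >= 2 else np.nan
            mean = float(np.mean(x))
            cv = 100.0 * sd / mean if n >= 2 and mean != 0 else np.nan
            rows.append(
                {
                    "strip": strip,
                    "variable": var,
                    "n": n,
                    "min": float(np.min(x)),
                    "max": float(np.max(x)),
                    "mean": mean,
                    "sd": sd,
                    "cv_pct": cv,
                    "median": float(np.median(x)),
                    "sd_defined": n >= 2,
                }
            )
    return pd.DataFrame(rows)


def verify_gradient(
    summaries: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Check that strip means increase strictly in strip order.

    Returns one row per variable with the per-strip means, the pairwise
    successive differences and a ``passed`` flag (strictly increasing means;
    ties fail — the method's premise is distinct fertility strata).
    """
    strips = sorted(summaries["strip"].unique())
    if len(strips) < 2:
        raise ValueError("gradient verification needs at least two strips")
    rows = []
    for var in variables:
        sub = summaries[summaries["variable"] == var]
        if len(sub) == 0:
            raise KeyError(f"missing variable: {var}")
        means = [float(sub[sub["strip"] == s]["mean"].iloc[0]) for s in strips]
        diffs = [b - a for a, b in zip(means, means[1:])]
        rows.append(
            {
                "variable": var,
                "strip_means": means,
                "successive_differences": diffs,
                "passed": all(d > 0 for d in diffs),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class YieldModelFit:
    """OLS fit of yield on uptake, soil-test, dose and manure predictors."""

    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    residuals: np.ndarray

    def predict(self, plots: pd.DataFrame) -> np.ndarray:
        X = plots[list(self.coefficients)].to_numpy(dtype=float)
        beta = np.array([self.coefficients[c] for c in self.coefficients])
        return self.intercept + X @ beta


def fit_yield_model(
    plots: pd.DataFrame,
    predictors: Sequence[str] = YIELD_MODEL_PREDICTORS,
    response: str = "yield_kg_ha",
) -> YieldModelFit:
    """Ordinary least squares of ``response`` on the ten standard predictors.

    Requires more plots than parameters (>= 12 for the default ten
    predictors plus intercept) and a full-rank design; a constant or
    collinear predictor raises :class:`CollinearPredictorError` naming it.
    """
    if len(plots) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} plots to fit {len(predictors)} predictors"
        )
    X = plots[list(predictors)].to_numpy(dtype=float)
    for i, col in enumerate(predictors):
        if np.ptp(X[:, i]) == 0:
            raise CollinearPredictorError(col)
    Xc = sm.add_constant(X, has_constant="add")
    rank = 1
    for i, col in enumerate(predictors):
        new_rank = np.linalg.matrix_rank(Xc[:, : i + 2])
        if new_rank == rank:
            raise CollinearPredictorError(col)
        rank = new_rank
    y = plots[response].to_numpy(dtype=float)
    res = sm.OLS(y, Xc).fit()
    r2 = 1.0 if np.ptp(y) == 0 else float(res.rsquared)
    return YieldModelFit(
        intercept=float(res.params[0]),
        coefficients={c: float(b) for c, b in zip(predictors, res.params[1:])},
        r_squared=r2,
        residuals=np.asarray(res.resid),
    )
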