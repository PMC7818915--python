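"""Thin wrapper around identity-link Gaussian linear fits.

All regressions in the package are ordinary linear models (an identity-link
Gaussian GLM is numerically an OLS fit); we use statsmodels OLS so that
coefficient confidence intervals use the exact t reference distribution at
the small sample sizes typical here. Coefficient significance is assessed
with Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, SingularFitError

__all__ = ["LinearFit", "fit_linear"]


@dataclass
class LinearFit:
    """An identity-link linear model fit.

    Attributes
    ----------
    params : pd.Series
        Coefficients, indexed by term name ("Intercept" first).
    bse : pd.Series
        Standard errors.
    pvalues : pd.Series
        Two-sided Wald p-values.
    conf_int : pd.DataFrame
        95% confidence intervals (columns ``lower``/``upper``).
    nobs : int
        Number of rows used in the fit.
    sm_results : object
        The underlying statsmodels results (for contrasts / diagnostics).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    nobs: int
    sm_results: object = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "ci_lower": self.conf_int["lower"],
                "ci_upper": self.conf_int["upper"],
            }
        )
        out.index.name = "term"
        return out


def fit_linear(y, X: pd.DataFrame, min_rows: int = 3) -> LinearFit:
    """OLS of ``y`` on the columns of ``X`` plus an intercept.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_rows`` complete rows.
    SingularFitError
        Zero-variance or collinear design.
    """
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if len(y) < min_rows:
        raise InsufficientDataError(
            f"need at least {min_rows} complete rows, got {len(y)}"
        )
    for col in X.columns:
        if np.isclose(X[col].var(ddof=0), 0.0):
            raise SingularFitError(f"predictor {col!r} has zero variance")
    design = sm.add_constant(X, has_constant="add").rename(
        columns={"const": "Intercept"}
    )
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise SingularFitError("collinear design matrix")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return LinearFit(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=ci,
        nobs=int(res.nobs),
        sm_results=res,
    )
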