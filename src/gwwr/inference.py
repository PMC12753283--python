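"""Hypothesis tests for the global Weibull regression model.

Simultaneous adequacy is tested with the Wilks likelihood-ratio statistic
``W = 2(l_full - l_null)`` (chi-square, df = number of covariates), or its
large-sample quadratic-form approximation ``B' [IF22]^{-1} B`` in the
slope estimates.  Individual covariates are tested with the Wald ratio
``Q_k = b_k / se(b_k)`` against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: object          # int, tuple, or None (normal reference)
    p_value: float
    alpha: float
    method: str = "likelihood"

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def wilks_simultaneous(full, null, alpha: float = 0.05) -> TestResult:
    """Likelihood-ratio test of all slopes being zero.

    ``full`` and ``null`` are fitted results on the same sample; df equals
    the number of covariates in the full model.
    """
    if full.nobs != null.nobs:
        raise ValueError("fits must share the same sample")
    W = 2.0 * (full.llf - null.llf)
    if W < -1e-6:
        raise ValueError(
            "full-model loglik below null loglik: optimizer failure")
    W = max(W, 0.0)
    df = full.sample.p
    p = float(stats.chi2.sf(W, df))
    return TestResult("wilks_simultaneous", float(W), df, p, alpha,
                      "likelihood")


def slope_block_cov(results) -> np.ndarray:
    """IF22: variance of the slopes, dropping shape and intercept."""
    return results.cov_params()[2:, 2:]


def wilks_quadratic_form(full, alpha: float = 0.05) -> TestResult:
    """Quadratic-form approximation W ~= B' [IF22]^{-1} B."""
    B = full.params.coef[1:]
    V = slope_block_cov(full)
    try:
        W = float(B @ np.linalg.solve(V, B))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular slope covariance: {e}")
    df = B.size
    p = float(stats.chi2.sf(W, df))
    return TestResult("wilks_simultaneous", W, df, p, alpha,
                      "quadratic_form")


def wald_partial(fit, k: int, alpha: float = 0.05) -> TestResult:
    """Two-sided Wald test of coefficient ``b_k`` (k = 0 tests the
    intercept); ``Q_k = b_k / se(b_k)`` referred to N(0, 1)."""
    coef = fit.params.coef
    if not 0 <= k < coef.size:
        raise IndexError(f"covariate index {k} out of range")
    var = fit.cov_params()[k + 1, k + 1]  # shape occupies slot 0
    if var <= 0:
        raise ValueError("nonpositive variance estimate")
    Q = float(coef[k] / np.sqrt(var))
    p = float(2.0 * stats.norm.sf(abs(Q)))
    name = "Intercept" if k == 0 else fit.sample.covariate_names[k - 1]
    return TestResult(f"wald[{name}]", Q, None, p, alpha, "quadratic_form")


def wald_table(fit, alpha: float = 0.05):
    """Wald tests for the intercept and every covariate, as a DataFrame."""
    import pandas as pd
    rows = []
    for k in range(fit.params.coef.size):
        t = wald_partial(fit, k, alpha)
        rows.append({
            "covariate": "Intercept" if k == 0 else
            fit.sample.covariate_names[k - 1],
            "estimate": fit.params.coef[k],
            "se": fit.bse[k + 1],
            "abs_Q": abs(t.statistic),
            "p_value": t.p_value,
            "significant": t.reject,
        })
    return pd.DataFrame(rows)
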