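"""Screening and goodness-of-fit diagnostics.

Pre-fit: variance inflation factors (multicollinearity) and the Glejser
test (absolute OLS residuals regressed on the covariates) as the spatial
heterogeneity screen.  Post-fit: BIC, GCV, McFadden pseudo-R2 and MAPE
for both the global and the geographically weighted model, plus backward
covariate elimination driven by the partial Wald tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import wald_table
from .model import WeibullRegression


def _ols_r2(ycol: np.ndarray, X: np.ndarray) -> float:
    """R-squared of an intercept-included least-squares regression."""
    Z = np.column_stack([np.ones(len(ycol)), X])
    beta, *_ = np.linalg.lstsq(Z, ycol, rcond=None)
    resid = ycol - Z @ beta
    tss = float(np.sum((ycol - ycol.mean()) ** 2))
    if tss <= 1e-12 * max(1.0, float(ycol @ ycol)):  # constant response
        return 0.0
    return 1.0 - float(resid @ resid) / tss


def vif(covariates, names=None, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factor 1/(1-Rk^2) per covariate.

    ``Rk^2`` comes from regressing covariate k (with intercept) on the
    remaining covariates.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than covariates")
    if names is None:
        names = [f"X{k + 1}" for k in range(p)]
    rows = []
    for k in range(p):
        col = X[:, k]
        if np.ptp(col) == 0:
            raise ValueError(f"constant covariate column: {names[k]}")
        others = np.delete(X, k, axis=1)
        r2 = _ols_r2(col, others) if p > 1 else 0.0
        r2 = min(r2, 1.0 - 1e-12)
        rows.append({"covariate": names[k], "Rk_squared": r2,
                     "vif": 1.0 / (1.0 - r2),
                     "flagged": 1.0 / (1.0 - r2) > flag_threshold})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlejserResult:
    statistic: float
    df: tuple
    p_value: float
    alpha: float

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


def glejser_test(sample, alpha: float = 0.05,
                 residuals: str = "ols") -> GlejserResult:
    """Glejser heterogeneity test.

    Absolute residuals of a regression of the response on the covariates
    are regressed (OLS, with intercept) back on the covariates; the
    overall F statistic with (p, n-p-1) df tests whether the residual
    scale varies with the covariates -- used here as the spatial
    heterogeneity screen.  ``residuals="wr_mean"`` takes residuals from
    the Weibull mean regression instead of the default OLS fit.
    """
    X = sample.covariates
    y = sample.response
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    if residuals == "ols":
        Z = np.column_stack([np.ones(n), X])
        beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
        if rank < Z.shape[1]:
            raise ValueError("rank-deficient design")
        e = np.abs(y - Z @ beta)
    elif residuals == "wr_mean":
        res = WeibullRegression(sample).fit()
        e = np.abs(y - res.predict_mean())
    else:
        raise ValueError(f"unknown residual source {residuals!r}")
    r2 = _ols_r2(e, X)
    df = (p, n - p - 1)
    if r2 >= 1.0 - 1e-12:
        Fg = np.inf
    else:
        Fg = (r2 / p) / ((1.0 - r2) / (n - p - 1))
    return GlejserResult(statistic=float(Fg), df=df,
                         p_value=float(stats.f.sf(Fg, *df)), alpha=alpha)


@dataclass(frozen=True)
class GOFReport:
    bic: float
    gcv: float
    mcfadden_r2: float
    mape_percent: float
    loglik: float
    K: int
    n: int

    def to_dict(self) -> dict:
        return {"bic": self.bic, "gcv": self.gcv,
                "mcfadden_r2": self.mcfadden_r2,
                "mape_percent": self.mape_percent, "loglik": self.loglik,
                "K": self.K, "n": self.n}


def _gwwr_own_site_loglik(gwwr) -> float:
    """Model-level GWWR log-likelihood: each observation contributes its
    own-site term delta_i*log h + log S at phi_hat(u_i)."""
    s = gwwr.sample
    total = 0.0
    for i, lf in enumerate(gwwr.local_fits):
        if lf is None:
            raise ValueError(f"local fit missing at site {i}")
        g = lf.params.shape
        y = s.censored_response[i]
        eta = float(lf.params.coef @ s.design[i])
        log_h = np.log(g) + (g - 1.0) * np.log(y) + eta
        log_S = -np.exp(g * np.log(y) + eta)
        total += s.delta[i] * log_h + log_S
    return float(total)


def _gwwr_mean_predictions(gwwr) -> np.ndarray:
    from scipy.special import gamma as gamma_fn
    s = gwwr.sample
    out = np.empty(s.n)
    for i, lf in enumerate(gwwr.local_fits):
        g = lf.params.shape
        out[i] = gamma_fn(1 + 1 / g) * np.exp(-float(lf.params.coef @ s.design[i]) / g)
    return out


def gof_report(fit, sample=None, *, events_only_mape: bool = False) -> GOFReport:
    """BIC, GCV, McFadden R2 and MAPE for a fitted global or GWWR model.

    MAPE compares mean-model predictions with the original (uncensored)
    responses, which are fully observed here; ``events_only_mape``
    restricts it to event rows.  GCV = n * RSS / (n - K)^2 on the same
    mean-scale residuals.  The GWWR log-likelihood sums each
    observation's own-site contribution; K = p + 2 in both cases.
    """
    from .gwmodel import GWWRResults
    if isinstance(fit, GWWRResults):
        sample = fit.sample
        ll = _gwwr_own_site_loglik(fit)
        mu = _gwwr_mean_predictions(fit)
        null_llf = WeibullRegression(sample).fit_null().llf
    else:
        sample = fit.sample if sample is None else sample
        ll = fit.llf
        mu = fit.predict_mean()
        null_llf = WeibullRegression(sample).fit_null().llf
    n, K = sample.n, sample.p + 2
    y = sample.response
    mask = sample.delta == 1 if events_only_mape else np.ones(n, bool)
    mape = 100.0 * float(np.mean(np.abs(y[mask] - mu[mask]) / y[mask]))
    rss = float(np.sum((y - mu) ** 2))
    gcv = n * rss / (n - K) ** 2
    mcfadden = 1.0 - ll / null_llf
    return GOFReport(bic=-2.0 * ll + K * np.log(n), gcv=gcv,
                     mcfadden_r2=mcfadden, mape_percent=mape, loglik=ll,
                     K=K, n=n)


def _subset_sample(sample, keep):
    from .data import SpatialSample
    return SpatialSample.from_arrays(
        site_id=sample.site_id, coords=sample.coords,
        response=sample.response, covariates=sample.covariates[:, keep],
        threshold=sample.threshold,
        covariate_names=[sample.covariate_names[k] for k in keep])


def backward_eliminate(sample, alpha_stay: float = 0.10):
    """Backward elimination on partial Wald p-values.

    Repeatedly drops the covariate with the largest p-value exceeding
    ``alpha_stay`` and refits.  The returned final model is the visited
    model with the lowest BIC among those whose retained covariates all
    meet the stay rule (the fully reduced model always qualifies).

    Returns ``(final_results, trace)`` where the trace is a DataFrame of
    every visited model.
    """
    keep = list(range(sample.p))
    trace_rows = []
    visited = []
    while True:
        sub = _subset_sample(sample, keep) if keep else _subset_sample(sample, [])
        res = WeibullRegression(sub).fit()
        if keep:
            wt = wald_table(res).iloc[1:]  # exclude the intercept row
            pvals = wt["p_value"].to_numpy()
        else:
            pvals = np.array([])
        all_stay = bool(np.all(pvals <= alpha_stay)) if pvals.size else True
        trace_rows.append({
            "covariates": tuple(sub.covariate_names),
            "bic": res.bic(), "loglik": res.llf,
            "max_p": float(pvals.max()) if pvals.size else np.nan,
            "all_meet_stay_rule": all_stay})
        visited.append((res, all_stay))
        if not keep or all_stay:
            break
        worst = int(np.argmax(pvals))
        del keep[worst]
    eligible = [r for r, ok in visited if ok]
    pool = eligible if eligible else [r for r, _ in visited]
    final = min(pool, key=lambda r: r.bic())
    return final, pd.DataFrame(trace_rows)
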