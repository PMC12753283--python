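"""Inference for the geographically weighted model.

Three stages: (1) a similarity test of whether location-varying
coefficients improve on the single global vector, (2) a simultaneous test
of all local slopes, and (3) per-site partial Wald tests from which the
map of locally influential covariates is built.

Both whole-model tests come in two flavours: a likelihood method summing
per-site weighted log-likelihood gaps, and a quadratic-form method summing
per-site forms in the slope estimates with the local slope covariance
(IF22).  The reference distribution is chi-square with ``n * p`` degrees
of freedom.  The quadratic-form method is the default, since its inputs
(local estimates and their variances) are the quantities the local fits
tabulate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import TestResult
from .model import loglik


def _local_slope_cov(lf) -> np.ndarray:
    """IF22 at a site: local varcov without the shape and intercept."""
    return lf.varcov[2:, 2:]


def _require_complete(gwwr):
    if any(lf is None for lf in gwwr.local_fits):
        raise ValueError("similarity/simultaneous tests need all local fits; "
                         f"failed sites: {[i for i, lf in enumerate(gwwr.local_fits) if lf is None]}")


def similarity_test(gwwr, global_results, alpha: float = 0.05,
                    method: str = "quadratic_form") -> TestResult:
    """GWWR-vs-WR similarity test, df = n*p.

    likelihood method: G = 2 sum_i (l_i(phi_hat(u_i)) - l_i(phi_hat)),
    where the global log-likelihood inside each gap is evaluated under the
    same spatial weights as the local fit (a nested comparison).
    quadratic-form method: G ~= sum_i C(u_i) with
    C(u_i) = (B_i - B)' [IF22_i]^{-1} (B_i - B).
    """
    _require_complete(gwwr)
    sample = gwwr.sample
    if global_results.sample.p != sample.p:
        raise ValueError("global and local fits have different covariates")
    n, p = sample.n, sample.p
    if method == "likelihood":
        phi_g = global_results.params.packed
        G = 0.0
        for lf in gwwr.local_fits:
            G += 2.0 * (lf.loglik - loglik(phi_g, sample, lf.weights))
        G = max(G, 0.0)
    elif method == "quadratic_form":
        B_global = global_results.params.coef[1:]
        G = 0.0
        for lf in gwwr.local_fits:
            dB = lf.params.coef[1:] - B_global
            G += float(dB @ np.linalg.solve(_local_slope_cov(lf), dB))
    else:
        raise ValueError(f"unknown method {method!r}")
    df = n * p
    return TestResult("similarity", float(G), df,
                      float(stats.chi2.sf(G, df)), alpha, method)


def simultaneous_test(gwwr, alpha: float = 0.05,
                      method: str = "quadratic_form") -> TestResult:
    """Test of all local slopes being zero, df = n*p.

    likelihood method: Gw = 2 sum_i (l_i(phi_hat(u_i)) - l_i(phi0_hat(u_i)))
    with a weighted shape-plus-intercept null fit per site.
    quadratic-form method: Gw ~= sum_i B_i' [IF22_i]^{-1} B_i.
    """
    _require_complete(gwwr)
    n, p = gwwr.sample.n, gwwr.sample.p
    if method == "likelihood":
        Gw = 0.0
        for i, lf in enumerate(gwwr.local_fits):
            _, ll0 = gwwr.local_null_fit(i)
            Gw += 2.0 * (lf.loglik - ll0)
        Gw = max(Gw, 0.0)
    elif method == "quadratic_form":
        Gw = 0.0
        for lf in gwwr.local_fits:
            B = lf.params.coef[1:]
            Gw += float(B @ np.linalg.solve(_local_slope_cov(lf), B))
    else:
        raise ValueError(f"unknown method {method!r}")
    df = n * p
    return TestResult("simultaneous", float(Gw), df,
                      float(stats.chi2.sf(Gw, df)), alpha, method)


def partial_tests(gwwr, alpha: float = 0.05) -> pd.DataFrame:
    """Per-site Wald tests W_k(u_i) = b_k(u_i) / se(b_k(u_i)).

    Returns one row per (site, covariate) with the statistic, two-sided
    normal p-value and the significance flag at ``alpha``.  Sites whose
    local variance is unusable are flagged, not fatal.
    """
    sample = gwwr.sample
    rows = []
    for i, lf in enumerate(gwwr.local_fits):
        for k, name in enumerate(sample.covariate_names, start=1):
            row = {"site_index": i, "site_id": sample.site_id[i],
                   "covariate": name}
            if lf is None:
                row.update(statistic=np.nan, p_value=np.nan,
                           significant=False, flagged=True)
            else:
                var = lf.varcov[k + 1, k + 1]
                if not np.isfinite(var) or var <= 0:
                    row.update(statistic=np.nan, p_value=np.nan,
                               significant=False, flagged=True)
                else:
                    W = lf.params.coef[k] / np.sqrt(var)
                    p = 2.0 * stats.norm.sf(abs(W))
                    row.update(statistic=float(W), p_value=float(p),
                               significant=bool(p < alpha), flagged=False)
            rows.append(row)
    return pd.DataFrame(rows)


def factor_grouping(table: pd.DataFrame):
    """Partition sites by their set of significant covariates.

    Returns ``(site_sets, groups)``: a site-index -> frozenset map and a
    list of (signature, sorted site list) groups in deterministic order
    (descending group size, then lexicographic signature).
    """
    site_sets = {}
    for i, sub in table.groupby("site_index"):
        sig = frozenset(sub.loc[sub["significant"], "covariate"])
        site_sets[int(i)] = sig
    buckets = {}
    for i, sig in site_sets.items():
        buckets.setdefault(sig, []).append(i)
    groups = sorted(((tuple(sorted(sig)), sorted(sites))
                     for sig, sites in buckets.items()),
                    key=lambda t: (-len(t[1]), t[0]))
    return site_sets, groups
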