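"""Geographically weighted Weibull regression (GWWR).

Each site ``i`` gets its own parameter vector ``phi(u_i)`` estimated by
maximising the spatially weighted censored log-likelihood

    l(phi(u_i)) = sum_j w_ij * (d_j [log g_i + (g_i - 1) log y_j + b_i'x_j]
                                - y_j**g_i * exp(b_i'x_j)),

where the kernel weights ``w_ij`` decay with the Euclidean distance
``d_ij`` at a per-site adaptive bandwidth ``a_i``.  The bandwidth is
chosen per site by minimising ``BIC(u_i) = -2 l(phi_hat(u_i)) + K log n``
over a candidate grid; an infinite bandwidth (all weights one, i.e. the
global model) competes as a candidate.  With all weights equal to one,
every local fit reduces exactly to the global WR fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model import (ConvergenceError, WeibullRegression, WRParams, hessian,
                    loglik, newton_mle)


def pairwise_distances(coords) -> np.ndarray:
    """Symmetric Euclidean distance matrix between site coordinates."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return cdist(coords, coords)


def kernel_weights(distances_row, bandwidth: float, kind: str = "gaussian") -> np.ndarray:
    """Kernel weights for one site's distance row.

    gaussian:  w = exp(-0.5 (d/a)^2)
    bisquare:  w = (1 - (d/a)^2)^2 for d <= a, else 0 (compact support)

    An infinite bandwidth returns unit weights (the global model).
    """
    d = np.asarray(distances_row, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    if np.isinf(bandwidth):
        return np.ones_like(d)
    r = d / bandwidth
    if kind == "gaussian":
        return np.exp(-0.5 * r**2)
    if kind == "bisquare":
        return np.where(d <= bandwidth, (1.0 - np.minimum(r, 1.0) ** 2) ** 2, 0.0)
    raise ValueError(f"unknown kernel kind: {kind!r}")


@dataclass(frozen=True)
class KernelConfig:
    """Spatial weighting configuration.

    ``candidate_grid=None`` uses the default rule: ``n_candidates``
    log-spaced bandwidths from the site's (p+2)-th nearest-neighbour
    distance up to twice the maximum pairwise distance.  With
    ``include_infinite`` the all-weights-one candidate competes too.
    """

    kind: str = "gaussian"
    bandwidth_mode: str = "per_site_bic"  # or "fixed"
    fixed_bandwidth: float = np.inf
    candidate_grid: tuple = None
    n_candidates: int = 40
    include_infinite: bool = True
    # replace the full-sample-size BIC penalty K*log(n) by K*log(sum w);
    # off by default (the full-n form is the documented definition)
    bic_effective_n: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "bisquare"):
            raise ValueError("kernel kind must be 'gaussian' or 'bisquare'")
        if self.candidate_grid is not None:
            g = np.asarray(self.candidate_grid, dtype=float)
            if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) < 0):
                raise ValueError("candidate grid must be positive and sorted")


@dataclass
class LocalFit:
    site_index: int
    bandwidth: float
    weights: np.ndarray
    params: WRParams
    loglik: float
    varcov: np.ndarray
    bic: float
    converged: bool
    bic_trace: list = field(default_factory=list)  # (bandwidth, bic) pairs

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.varcov))


def local_loglik(phi, sample, weights):
    """Weighted log-likelihood (delegates to the shared kernel of the
    global model; unit weights reproduce it exactly)."""
    return loglik(phi, sample, weights)


def local_fit(sample, site_index, bandwidth, kernel: KernelConfig,
              init=None, distances=None) -> LocalFit:
    """Locally weighted MLE at one site for a given bandwidth."""
    if distances is None:
        distances = pairwise_distances(sample.coords)
    w = kernel_weights(distances[site_index], bandwidth, kernel.kind)
    _check_identified(sample, w)
    phi, info = newton_mle(sample, weights=w, init=init)
    H = hessian(phi, sample, w)
    try:
        varcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        varcov = np.full_like(H, np.nan)
    K = sample.p + 2
    n_pen = float(w.sum()) if kernel.bic_effective_n else sample.n
    bic = -2.0 * info["loglik"] + K * np.log(n_pen)
    return LocalFit(site_index=site_index, bandwidth=float(bandwidth),
                    weights=w, params=WRParams.from_packed(phi),
                    loglik=info["loglik"], varcov=varcov, bic=bic,
                    converged=info["converged"])


class UnderIdentifiedError(ConvergenceError):
    pass


def _check_identified(sample, w) -> None:
    # weighted event mass must support p+2 parameters
    if float(w @ sample.delta) < sample.p + 2:
        raise UnderIdentifiedError(
            "weighted event mass below p+2: bandwidth too small")


def default_candidate_grid(sample, site_index, kernel: KernelConfig,
                           distances=None) -> np.ndarray:
    """Log-spaced bandwidth candidates from the (p+2)-th nearest-neighbour
    distance at the site to twice the maximum pairwise distance."""
    if distances is None:
        distances = pairwise_distances(sample.coords)
    d = np.sort(distances[site_index])
    k = min(sample.p + 2, d.size - 1)
    lo = max(d[k], 1e-9 * max(d.max(), 1.0))
    hi = 2.0 * distances.max()
    if not hi > lo:
        hi = lo * 10.0
    return np.geomspace(lo, hi, kernel.n_candidates)


def optimize_bandwidth(sample, site_index, kernel: KernelConfig,
                       grid=None, init=None, distances=None):
    """Pick the bandwidth minimising the local BIC at one site.

    Returns ``(bandwidth, trace)`` where the trace lists every evaluated
    ``(bandwidth, bic)`` pair (NaN BIC marks an ineligible candidate).
    Ties break toward the larger bandwidth.
    """
    if distances is None:
        distances = pairwise_distances(sample.coords)
    if grid is None:
        grid = (np.asarray(kernel.candidate_grid, float)
                if kernel.candidate_grid is not None
                else default_candidate_grid(sample, site_index, kernel,
                                            distances))
    candidates = list(np.asarray(grid, dtype=float))
    if kernel.include_infinite:
        candidates.append(np.inf)
    best_a, best_bic, trace = None, np.inf, []
    for a in candidates:
        try:
            lf = local_fit(sample, site_index, a, kernel, init=init,
                           distances=distances)
            bic = lf.bic if lf.converged else np.nan
        except ConvergenceError:
            bic = np.nan
        trace.append((float(a), float(bic)))
        if np.isfinite(bic) and bic <= best_bic + 1e-9:
            best_a, best_bic = a, min(bic, best_bic)
    if best_a is None:
        raise UnderIdentifiedError(
            f"no eligible bandwidth candidate at site {site_index}")
    return float(best_a), trace


class GWWR:
    """Geographically weighted Weibull regression model.

    ``fit()`` runs the per-site bandwidth search (unless the kernel is in
    fixed-bandwidth mode) and the locally weighted MLE at every site,
    warm-starting each local fit from the global estimate.
    """

    def __init__(self, sample, kernel: KernelConfig = None):
        bad = sample.validate()
        if bad:
            raise ValueError(f"invalid sample: {bad}")
        self.sample = sample
        self.kernel = kernel or KernelConfig()
        self.distances = pairwise_distances(sample.coords)

    @classmethod
    def from_dataframe(cls, df, threshold: float, covariate_columns=None,
                       kernel: KernelConfig = None):
        from .data import SpatialSample
        return cls(SpatialSample.from_dataframe(df, threshold,
                                                covariate_columns), kernel)

    def fit(self, max_failure_fraction: float = 0.2) -> "GWWRResults":
        global_res = WeibullRegression(self.sample).fit()
        init = global_res.params.packed
        locals_, failures = [], []
        for i in range(self.sample.n):
            try:
                if self.kernel.bandwidth_mode == "fixed":
                    a, trace = self.kernel.fixed_bandwidth, []
                else:
                    a, trace = optimize_bandwidth(
                        self.sample, i, self.kernel, init=init,
                        distances=self.distances)
                lf = local_fit(self.sample, i, a, self.kernel, init=init,
                               distances=self.distances)
                lf.bic_trace = trace
                locals_.append(lf)
            except ConvergenceError as e:
                failures.append((i, str(e)))
                locals_.append(None)
        if len(failures) > max_failure_fraction * self.sample.n:
            raise ConvergenceError(
                f"{len(failures)} of {self.sample.n} local fits failed: "
                f"{failures[:3]}")
        return GWWRResults(self, locals_, global_res, failures)


class GWWRResults:
    """Per-site local fits plus the global fit for comparison tests."""

    def __init__(self, model: GWWR, local_fits, global_results, failures):
        self.model = model
        self.local_fits = local_fits
        self.global_results = global_results
        self.failures = failures

    @property
    def sample(self):
        return self.model.sample

    @property
    def converged_fits(self) -> list:
        return [lf for lf in self.local_fits if lf is not None]

    @property
    def bandwidths(self) -> np.ndarray:
        return np.array([lf.bandwidth if lf is not None else np.nan
                         for lf in self.local_fits])

    def coef_matrix(self) -> np.ndarray:
        """n x (p+2) matrix of packed local estimates (NaN for failures)."""
        out = np.full((self.sample.n, self.sample.p + 2), np.nan)
        for i, lf in enumerate(self.local_fits):
            if lf is not None:
                out[i] = lf.params.packed
        return out

    def local_null_fit(self, site_index: int):
        """Weighted shape-plus-intercept-only fit at one site (used by the
        simultaneous test's likelihood method)."""
        from .data import SpatialSample
        s = self.sample
        lf = self.local_fits[site_index]
        null_sample = SpatialSample.from_arrays(
            site_id=s.site_id, coords=s.coords, response=s.response,
            covariates=np.empty((s.n, 0)), threshold=s.threshold,
            covariate_names=[])
        phi, info = newton_mle(null_sample, weights=lf.weights)
        return phi, info["loglik"]

    # --- inference / downstream conveniences -------------------------
    def similarity_test(self, alpha=0.05, method="quadratic_form"):
        from .gwinference import similarity_test
        return similarity_test(self, self.global_results, alpha, method)

    def simultaneous_test(self, alpha=0.05, method="quadratic_form"):
        from .gwinference import simultaneous_test
        return simultaneous_test(self, alpha, method)

    def partial_tests(self, alpha=0.05):
        from .gwinference import partial_tests
        return partial_tests(self, alpha)

    def site_measures(self):
        from .interpretation import site_measures
        return site_measures(self)

    def local_params_table(self, alpha: float = 0.05):
        """Table-6-shaped frame: per site bandwidth, estimates, |W|, p."""
        import pandas as pd
        from scipy.stats import norm
        rows = []
        names = ["Intercept"] + list(self.sample.covariate_names)
        for i, lf in enumerate(self.local_fits):
            row = {"site_id": self.sample.site_id[i], "site_index": i}
            if lf is None:
                rows.append(row)
                continue
            row["bandwidth"] = lf.bandwidth
            row["shape"] = lf.params.shape
            se = lf.bse
            for k, nm in enumerate(names):
                b = lf.params.coef[k]
                W = b / se[k + 1]
                row[f"b[{nm}]"] = b
                row[f"absW[{nm}]"] = abs(W)
                row[f"p[{nm}]"] = 2 * norm.sf(abs(W))
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_ok = len(self.converged_fits)
        bw = self.bandwidths
        finite = bw[np.isfinite(bw)]
        lines = [
            "Geographically weighted Weibull regression",
            f"  n sites = {self.sample.n}, local fits converged = {n_ok}, "
            f"failures = {len(self.failures)}",
            f"  kernel = {self.model.kernel.kind}, "
            f"infinite-bandwidth sites = {int(np.isinf(bw).sum())}",
        ]
        if finite.size:
            lines.append(f"  finite bandwidths: min {finite.min():.4g}, "
                         f"median {np.median(finite):.4g}, "
                         f"max {finite.max():.4g}")
        g = self.global_results
        lines.append(f"  global fit: shape {g.params.shape:.4f}, "
                     f"loglik {g.llf:.4f}")
        return "\n".join(lines)
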