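"""Global censored Weibull regression (WR): likelihood, analytic
derivatives, damped Newton-Raphson MLE, and the fitted-model results
object.

Model
-----
The response follows a scale-shape Weibull with shape ``gamma`` and
rate-style scale ``lam(x) = exp(b' x)`` (``x`` includes a leading 1), so
the hazard is ``gamma * y**(gamma-1) * exp(b' x)`` -- a proportional
hazards structure.  With right censoring at ``y*`` (event indicator
``delta``) the log-likelihood is

    l(phi) = sum_i  d_i * [log g + (g-1) log y_i + b'x_i]
                    - y_i**g * exp(b'x_i),

with parameter vector ``phi = [gamma, b0, ..., bp]`` (shape first).  The
same expressions with per-observation weights ``w_ij`` serve the local
(geographically weighted) model, so all likelihood routines here accept
an optional weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn

from .distributions import WeibullParams


@dataclass(frozen=True)
class WRParams:
    """Shape-first packed parameters of a Weibull regression model."""

    shape: float
    coef: np.ndarray  # length p+1, [b0, b1, ..., bp]

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise ValueError("shape must be positive")
        object.__setattr__(self, "coef", np.asarray(self.coef, dtype=float))

    @property
    def packed(self) -> np.ndarray:
        return np.concatenate([[self.shape], self.coef])

    @classmethod
    def from_packed(cls, phi) -> "WRParams":
        phi = np.asarray(phi, dtype=float)
        return cls(shape=float(phi[0]), coef=phi[1:].copy())


def _unpack(phi):
    phi = np.asarray(phi, dtype=float)
    return float(phi[0]), phi[1:]


def _prepare(sample):
    y = sample.censored_response
    return y, np.log(y), sample.delta.astype(float), sample.design


def loglik(phi, sample, weights=None) -> float:
    """(Weighted) censored Weibull regression log-likelihood."""
    g, b = _unpack(phi)
    y, logy, d, X = _prepare(sample)
    if g <= 0:
        return -np.inf
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    eta = X @ b
    mu = np.exp(g * logy + eta)  # y^g * exp(b'x), computed in log space
    ll = w @ (d * (np.log(g) + (g - 1.0) * logy + eta) - mu)
    return float(ll)


def gradient(phi, sample, weights=None) -> np.ndarray:
    """Analytic gradient, shape component first."""
    g, b = _unpack(phi)
    y, logy, d, X = _prepare(sample)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    mu = np.exp(g * logy + X @ b)
    dg = w @ (d * (1.0 / g + logy) - mu * logy)
    db = X.T @ (w * (d - mu))
    return np.concatenate([[dg], db])


def hessian(phi, sample, weights=None) -> np.ndarray:
    """Analytic Hessian of the log-likelihood (exactly symmetric)."""
    g, b = _unpack(phi)
    y, logy, d, X = _prepare(sample)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    mu = np.exp(g * logy + X @ b)
    h_gg = -np.sum(w * (d / g**2 + mu * logy**2))
    h_gb = -X.T @ (w * mu * logy)
    M = (X * (w * mu)[:, None]).T @ X
    h_bb = -(M + M.T) / 2.0  # enforce exact symmetry
    k = X.shape[1] + 1
    H = np.empty((k, k))
    H[0, 0] = h_gg
    H[0, 1:] = h_gb
    H[1:, 0] = h_gb
    H[1:, 1:] = h_bb
    return H


def _default_init(sample, weights=None) -> np.ndarray:
    """Exponential moment start: gamma=1, b0=log(sum d / sum y), slopes 0."""
    y, _, d, X = _prepare(sample)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)
    num, den = float(w @ d), float(w @ y)
    b0 = np.log(max(num, 1e-8) / den)
    phi = np.zeros(X.shape[1] + 1)
    phi[0], phi[1] = 1.0, b0
    return phi


class ConvergenceError(RuntimeError):
    pass


def newton_mle(sample, weights=None, init=None, *, tol_grad: float = 1e-6,
               tol_step: float = 1e-8, max_iter: int = 100,
               max_halvings: int = 30):
    """Damped Newton-Raphson maximiser of the (weighted) log-likelihood.

    Step-halving keeps the shape positive and the log-likelihood
    nondecreasing; a singular or indefinite Hessian is ridge-stabilised
    (1e-8 * I escalating tenfold up to 1e-2) before declaring failure.

    Returns ``(phi_hat, info)`` with the convergence record in ``info``.
    """
    d = sample.delta.astype(float)
    w = np.ones(sample.n) if weights is None else np.asarray(weights, float)
    if float(w @ d) <= 0:
        raise ConvergenceError("no (weighted) events: likelihood unbounded")
    phi = _default_init(sample, weights) if init is None else np.asarray(init, float).copy()
    ll = loglik(phi, sample, w)
    halvings_total = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = gradient(phi, sample, w)
        if np.max(np.abs(v)) < tol_grad:
            converged = True
            break
        H = hessian(phi, sample, w)
        step = None
        ridge = 0.0
        while True:
            try:
                step = np.linalg.solve(H - ridge * np.eye(H.shape[0]), v)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and np.all(np.isfinite(step)):
                break
            ridge = 1e-8 if ridge == 0.0 else ridge * 10.0
            if ridge > 1e-2:
                raise ConvergenceError("singular Hessian beyond ridge budget")
        # line search: halve until loglik increases and shape stays positive
        alpha = 1.0
        for _ in range(max_halvings):
            cand = phi - alpha * step
            if cand[0] > 0:
                ll_cand = loglik(cand, sample, w)
                if np.isfinite(ll_cand) and ll_cand >= ll - 1e-12:
                    break
            alpha *= 0.5
            halvings_total += 1
        else:
            converged = np.max(np.abs(v)) < 1e-4  # stalled near optimum
            break
        delta_phi = phi - cand
        phi, ll = cand, loglik(cand, sample, w)
        if np.max(np.abs(delta_phi)) < tol_step:
            converged = np.max(np.abs(gradient(phi, sample, w))) < 1e-3
            break
    info = {
        "iterations": it,
        "converged": bool(converged),
        "step_halvings": halvings_total,
        "loglik": ll,
        "gradient": gradient(phi, sample, w),
    }
    return phi, info


class WeibullRegression:
    """Censored Weibull regression model (statsmodels-style).

    Parameters
    ----------
    sample : SpatialSample
        Observations with censored response, event indicator and design.

    Examples
    --------
    >>> model = WeibullRegression(sample)
    >>> res = model.fit()
    >>> res.summary()
    """

    def __init__(self, sample):
        bad = sample.validate()
        if bad:
            raise ValueError(f"invalid sample: {bad}")
        self.sample = sample

    @classmethod
    def from_dataframe(cls, df, threshold: float, covariate_columns=None):
        from .data import SpatialSample
        return cls(SpatialSample.from_dataframe(df, threshold,
                                                covariate_columns))

    def loglike(self, phi, weights=None):
        return loglik(phi, self.sample, weights)

    def score(self, phi, weights=None):
        return gradient(phi, self.sample, weights)

    def hessian(self, phi, weights=None):
        return hessian(phi, self.sample, weights)

    def fit(self, init=None, **kwargs) -> "WeibullRegressionResults":
        phi, info = newton_mle(self.sample, init=init, **kwargs)
        return WeibullRegressionResults(self, phi, info)

    def fit_null(self, **kwargs) -> "WeibullRegressionResults":
        """Intercept-plus-shape-only fit (the nested null model)."""
        from .data import SpatialSample
        s = self.sample
        null_sample = SpatialSample.from_arrays(
            site_id=s.site_id, coords=s.coords, response=s.response,
            covariates=np.empty((s.n, 0)), threshold=s.threshold,
            covariate_names=[])
        phi, info = newton_mle(null_sample, **kwargs)
        return WeibullRegressionResults(WeibullRegression(null_sample), phi, info)


class WeibullRegressionResults:
    """MLE results: estimates, observed-information variances, summary."""

    def __init__(self, model: WeibullRegression, phi, info, weights=None):
        self.model = model
        self.params = WRParams.from_packed(phi)
        self.weights = weights
        self.llf = info["loglik"]
        self.iterations = info["iterations"]
        self.converged = info["converged"]
        self.step_halvings = info.get("step_halvings", 0)
        self.score_at_opt = info["gradient"]

    @property
    def sample(self):
        return self.model.sample

    @property
    def nobs(self) -> int:
        return self.sample.n

    @property
    def k_params(self) -> int:
        return self.params.packed.size

    @property
    def param_names(self) -> list:
        return ["shape", "Intercept"] + list(self.sample.covariate_names)

    def hessian_at_opt(self) -> np.ndarray:
        return hessian(self.params.packed, self.sample, self.weights)

    def cov_params(self) -> np.ndarray:
        """Inverse observed information, var(phi_hat) = -H(phi_hat)^{-1}."""
        return np.linalg.inv(-self.hessian_at_opt())

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params()))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        p, se = self.params.packed, self.bse
        return np.column_stack([p - z * se, p + z * se])

    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.nobs)

    def params_at(self, x_row) -> WeibullParams:
        """Site-specific distribution parameters at one design row."""
        x = np.asarray(x_row, dtype=float)
        return WeibullParams(shape=self.params.shape,
                             rate_scale=float(np.exp(self.params.coef @ x)))

    def predict(self, design=None, y=None) -> "np.recarray":
        """Evaluate S, F, h, mu (and f) over design rows and response values.

        ``design`` rows must include the leading intercept column; ``y``
        is broadcast against the rows.  Returns a pandas DataFrame.
        """
        import pandas as pd
        X = self.sample.design if design is None else np.atleast_2d(
            np.asarray(design, float))
        if X.shape[1] != self.params.coef.size:
            raise ValueError("design columns do not match coefficient length")
        yv = self.sample.censored_response if y is None else np.asarray(y, float)
        yv = np.broadcast_to(yv, (X.shape[0],)) if yv.ndim <= 1 else yv
        g = self.params.shape
        lam = np.exp(X @ self.params.coef)
        S = np.exp(-lam * yv**g)
        h = lam * g * yv ** (g - 1.0)
        mu = gamma_fn(1.0 + 1.0 / g) * np.exp(-(X @ self.params.coef) / g)
        return pd.DataFrame({"y": yv, "S": S, "F": 1.0 - S, "h": h,
                             "mu": mu, "f": h * S})

    def predict_mean(self, design=None) -> np.ndarray:
        X = self.sample.design if design is None else np.atleast_2d(
            np.asarray(design, float))
        g = self.params.shape
        return gamma_fn(1.0 + 1.0 / g) * np.exp(-(X @ self.params.coef) / g)

    def summary(self) -> str:
        from scipy.stats import norm
        se = self.bse
        phi = self.params.packed
        lines = [
            "Censored Weibull regression (MLE)",
            f"  n = {self.nobs}, events = {int(self.sample.delta.sum())}, "
            f"loglik = {self.llf:.4f}, BIC = {self.bic():.4f}",
            f"  converged: {self.converged} in {self.iterations} iterations",
            f"{'param':>12} {'estimate':>12} {'std err':>10} {'z':>8} {'P>|z|':>10}",
        ]
        for name, est, s in zip(self.param_names, phi, se):
            z = est / s
            pv = 2 * (1 - norm.cdf(abs(z)))
            lines.append(f"{name:>12} {est:>12.4f} {s:>10.4f} {z:>8.4f} {pv:>10.4g}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<WeibullRegressionResults shape={self.params.shape:.4f} "
                f"llf={self.llf:.4f} converged={self.converged}>")
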