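"""Observation container, censoring transform, validation, and CSV I/O.

A :class:`SpatialSample` holds one row per monitoring site: an identifier,
planar coordinates ``(u, v)``, the positive response (e.g. dissolved oxygen
in ppm), the censored response and event indicator produced by the
threshold rule, and the covariate matrix.

Censoring convention: values *below* the quality threshold ``y*`` are the
events (``delta = 1``, e.g. water-quality degradation); values at or above
``y*`` are recorded as ``y*`` with ``delta = 0`` (right-censored).  Ties
``y == y*`` are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("site_id", "u", "v", "y")


def apply_censoring(raw_response, threshold: float):
    """Censor a raw positive response at ``threshold``.

    Returns ``(censored_response, delta)`` where values ``< threshold``
    pass through with ``delta = 1`` and values ``>= threshold`` are
    replaced by the threshold with ``delta = 0``.  Idempotent.
    """
    y = np.asarray(raw_response, dtype=float)
    if np.any(y <= 0):
        raise ValueError("responses must be strictly positive")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    delta = (y < threshold).astype(int)
    return np.where(delta == 1, y, threshold), delta


@dataclass(frozen=True)
class CensorSummary:
    n: int
    events: int

    @property
    def event_fraction(self) -> float:
        return self.events / self.n


@dataclass
class SpatialSample:
    """Censored spatial regression sample.

    Construct via :meth:`from_arrays` or :meth:`from_dataframe` so the
    censoring transform and the design matrix (leading intercept column)
    are built consistently.
    """

    site_id: np.ndarray
    coords: np.ndarray           # n x 2
    response: np.ndarray         # raw y_i > 0
    censored_response: np.ndarray
    delta: np.ndarray            # 1 = event (y < y*), 0 = censored
    covariates: np.ndarray       # n x p
    covariate_names: list
    threshold: float

    @property
    def n(self) -> int:
        return self.response.size

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def design(self) -> np.ndarray:
        """n x (p+1) matrix with a leading column of ones."""
        return np.column_stack([np.ones(self.n), self.covariates])

    @classmethod
    def from_arrays(cls, site_id, coords, response, covariates, threshold,
                    covariate_names=None) -> "SpatialSample":
        response = np.asarray(response, dtype=float)
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != response.size:
            covariates = covariates.T
        cens, delta = apply_censoring(response, threshold)
        if covariate_names is None:
            covariate_names = [f"X{k + 1}" for k in range(covariates.shape[1])]
        return cls(
            site_id=np.asarray(site_id).astype(str),
            coords=np.asarray(coords, dtype=float).reshape(-1, 2),
            response=response,
            censored_response=cens,
            delta=np.asarray(delta, dtype=int),
            covariates=covariates,
            covariate_names=list(covariate_names),
            threshold=float(threshold),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, threshold: float,
                       covariate_columns=None) -> "SpatialSample":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if covariate_columns is None:
            covariate_columns = [c for c in df.columns if c not in REQUIRED_COLUMNS]
        return cls.from_arrays(
            site_id=df["site_id"].to_numpy(),
            coords=df[["u", "v"]].to_numpy(dtype=float),
            response=df["y"].to_numpy(dtype=float),
            covariates=df[covariate_columns].to_numpy(dtype=float),
            threshold=threshold,
            covariate_names=list(covariate_columns),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"site_id": self.site_id,
                            "u": self.coords[:, 0], "v": self.coords[:, 1],
                            "y": self.response})
        for k, name in enumerate(self.covariate_names):
            out[name] = self.covariates[:, k]
        return out

    def summarize_censoring(self) -> CensorSummary:
        return CensorSummary(n=self.n, events=int(self.delta.sum()))

    def validate(self) -> list:
        """Return a list of invariant violations (empty means valid)."""
        v = []
        n, p = self.n, self.p
        if np.any(self.response <= 0):
            v.append("nonpositive response")
        if not np.all(np.isfinite(self.coords)):
            v.append("non-finite coordinates")
        if not np.all(np.isfinite(self.covariates)):
            v.append("non-finite covariates")
        if n < p + 2:
            v.append("insufficient observations (need n >= p+2)")
        ev = self.delta == 1
        if np.any(self.censored_response[ev] != self.response[ev]):
            v.append("event rows must keep their raw response")
        if np.any(self.censored_response[~ev] != self.threshold):
            v.append("censored rows must equal the threshold")
        if np.any((self.response < self.threshold) != ev):
            v.append("delta inconsistent with threshold rule")
        # duplicate coordinates are legal (zero distances give weight 1);
        # surfaced as information only, not a violation
        return v


def read_sample(path, threshold: float, covariate_columns=None) -> SpatialSample:
    """Read the package's CSV schema: site_id,u,v,y,<covariates...>."""
    df = pd.read_csv(path)
    return SpatialSample.from_dataframe(df, threshold=threshold,
                                        covariate_columns=covariate_columns)


def write_sample(sample: SpatialSample, path) -> None:
    sample.to_dataframe().to_csv(path, index=False)
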