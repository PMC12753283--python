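import numpy as np
import pytest

from gwwr import SpatialSample
from gwwr.simulate import (global_truth_config, river_study_fixture, simulate)


@pytest.fixture(scope="session")
def fixture27():
    """Deterministic 27-site, 10-covariate study-scale sample."""
    return river_study_fixture(seed=0)


@pytest.fixture(scope="session")
def small_sample():
    """30-row, 2-covariate censored sample with a global truth."""
    cfg = global_truth_config(n_sites=30, seed=7)
    sample, _ = simulate(cfg)
    return sample


@pytest.fixture(scope="session")
def medium_sample():
    """400-row sample from the global-truth configuration."""
    cfg = global_truth_config(n_sites=400, seed=11)
    sample, _ = simulate(cfg)
    return sample


def make_sample(y, delta, X, coords=None, threshold=None):
    """Build a SpatialSample from explicit censored data.

    ``threshold`` defaults to just above the max so that the requested
    delta pattern is reproduced by shifting censored values to the
    threshold.
    """
    y = np.asarray(y, float)
    delta = np.asarray(delta, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    if threshold is None:
        threshold = float(y[delta == 0].min()) if np.any(delta == 0) \
            else float(y.max() * 10)
    raw = np.where(delta == 1, y, threshold * (1 + 1e-9))
    if coords is None:
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 1, (n, 2))
    s = SpatialSample.from_arrays(
        site_id=[f"t{i}" for i in range(n)], coords=coords,
        response=raw, covariates=X, threshold=threshold)
    assert np.array_equal(s.delta, delta)
    return s
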