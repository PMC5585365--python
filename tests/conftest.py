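import numpy as np
import pytest

from rert.data_io import BINARY, QUANTITATIVE, Cohort, CovariateSpec


def make_cohort(X, y, stratum=None, kinds=None, names=None):
    """Convenience constructor for quantitative-covariate cohorts."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    specs = []
    for j, name in enumerate(names):
        kind = (kinds or {}).get(name, QUANTITATIVE)
        levels = ("no", "yes") if kind == BINARY else None
        specs.append(CovariateSpec(name, kind, levels=levels))
    stratum = (
        np.array(["all"] * n, dtype=object)
        if stratum is None
        else np.asarray(stratum, dtype=object)
    )
    return Cohort(specs, X, np.asarray(y), stratum)


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture
def small_signal_cohort(rng):
    """n=120, one strong driver x0 plus three noise covariates."""
    n = 120
    X = rng.normal(size=(n, 4))
    y = (X[:, 0] >= 0.25).astype(int)
    y = np.where(rng.random(n) < 0.08, 1 - y, y)
    strat = np.where(rng.random(n) < 0.85, "endometrioid", "other").astype(object)
    return make_cohort(X, y, stratum=strat)
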