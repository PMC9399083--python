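"""Shared fixtures: specs, synthetic cohorts, and small fitted models."""

import numpy as np
import pytest

import ginvest as gv
from ginvest.engine import EngineData, EnginePriors, GibbsEngine


@pytest.fixture(scope="session")
def default_spec():
    return gv.build_default_spec()


@pytest.fixture(scope="session")
def truth():
    return gv.default_truth()


@pytest.fixture(scope="session")
def small_cohort(truth):
    return gv.generate_cohort(truth, 400, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick 2-chain fit at n=400 reused by structure/diagnostic tests."""
    model = gv.InvestmentModel(small_cohort.table)
    res = model.fit(chains=2, iterations=2500, burnin=1000, thin=3, seed=7)
    return model, res


def make_continuous_engine(yobs, X, lam_fixed, psi, beta_var=100.0**2):
    """1+ factor engine with continuous indicators, fixed loadings and fixed
    latent covariance — the linear-Gaussian degenerate mode."""
    yobs = np.asarray(yobs, dtype=float)
    n, J = yobs.shape
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    G = psi.shape[0]
    X = [np.asarray(x, dtype=float) for x in (X if isinstance(X, list) else [X])]
    data = EngineData(
        codes=np.zeros((n, J), dtype=np.int64),
        mask=np.ones((n, J), dtype=bool),
        item_factor=np.zeros(J, dtype=np.int64) if G == 1 else np.arange(J, dtype=np.int64),
        item_ncat=np.zeros(J, dtype=np.int64),
        lam_group=np.full(J, -1, dtype=np.int64),
        lam_fixed=np.asarray(lam_fixed, dtype=float),
        tau_group=np.full(J, -1, dtype=np.int64),
        X=X,
        yobs=yobs,
    )
    return GibbsEngine(data, EnginePriors(beta_var=beta_var),
                       sample_psi=False, psi_fixed=psi)


def make_binary_probit_engine(y, x, psi_fixed=1.0):
    """1 factor, 1 binary indicator (marker loading 1, one free threshold),
    1 predictor column — the minimal ordinal-probit reduction."""
    y = np.asarray(y, dtype=np.int64)
    n = y.size
    data = EngineData(
        codes=y.reshape(-1, 1),
        mask=np.ones((n, 1), dtype=bool),
        item_factor=np.zeros(1, dtype=np.int64),
        item_ncat=np.array([2], dtype=np.int64),
        lam_group=np.array([-1], dtype=np.int64),
        lam_fixed=np.array([1.0]),
        tau_group=np.array([0], dtype=np.int64),
        X=[np.asarray(x, dtype=float).reshape(n, -1)],
        tau_group_names=["item"],
    )
    return GibbsEngine(data, EnginePriors(), sample_psi=False,
                       psi_fixed=np.array([[float(psi_fixed)]]))
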