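"""Gibbs engine unit tests: each full-conditional update against an
independent analytic or Monte-Carlo oracle, plus chain orchestration."""

import numpy as np
from scipy import stats

import ginvest as gv
from ginvest import _kernels
from ginvest.engine import EngineData, EnginePriors, GibbsEngine, build_engine
from ginvest.spec import ChainConfig

from conftest import make_binary_probit_engine, make_continuous_engine


# ----------------------------------------------------------------------
# truncated-normal draws (latent response update)
# ----------------------------------------------------------------------
def test_truncnorm_lower_category_moment():
    """Category below tau=0 at zero mean: draws <= 0, mean -> -sqrt(2/pi)."""
    rng = np.random.default_rng(0)
    d = np.array([_kernels.truncnorm_draw(0.0, -np.inf, 0.0, u)
                  for u in rng.random(40_000)])
    assert d.max() <= 0.0
    assert abs(d.mean() + np.sqrt(2 / np.pi)) < 0.01


def test_truncnorm_inactive_in_the_limit():
    """Top category with mean far above the cut: truncation is inactive."""
    rng = np.random.default_rng(1)
    d = np.array([_kernels.truncnorm_draw(10.0, 0.0, np.inf, u)
                  for u in rng.random(20_000)])
    assert abs(d.mean() - 10.0) < 0.03
    assert abs(d.std() - 1.0) < 0.02


def test_truncnorm_interval_matches_rejection_oracle():
    """Draws on (-0.2, 0.3) match rejection sampling from N(0,1) (KS test)."""
    rng = np.random.default_rng(2)
    d = np.array([_kernels.truncnorm_draw(0.0, -0.2, 0.3, u)
                  for u in rng.random(5_000)])
    ref = stats.truncnorm(-0.2, 0.3)
    ks = stats.kstest(d, ref.cdf)
    assert ks.pvalue > 0.001


def test_update_ystar_leaves_masked_cells_untouched():
    y = np.array([0], dtype=np.int64).reshape(1, 1)
    eng = make_binary_probit_engine(y.ravel(), np.zeros((1, 1)))
    eng.data.mask[:] = False
    rng = np.random.default_rng(0)
    state = eng.init_state(rng)
    state.ystar[0, 0] = 123.0
    eng.sample_latent_responses(state, rng)
    assert state.ystar[0, 0] == 123.0


# ----------------------------------------------------------------------
# factor-score update
# ----------------------------------------------------------------------
def test_factor_conditional_precision_weighting():
    """1 indicator, lambda=1, zeta=1, y*=2 -> posterior N(1.0, 0.5)."""
    eng = make_continuous_engine(yobs=[[2.0]], X=np.zeros((1, 1)),
                                 lam_fixed=[1.0], psi=[[1.0]])
    rng = np.random.default_rng(3)
    state = eng.init_state(rng)
    draws = np.empty(30_000)
    for k in range(draws.size):
        eng.sample_factors(state, rng)
        draws[k] = state.eta[0, 0]
    assert abs(draws.mean() - 1.0) < 0.02
    assert abs(draws.var() - 0.5) < 0.02


def test_factor_conditional_no_data_limit():
    """All indicators masked: eta ~ N(mu, Psi) exactly."""
    psi = np.array([[1.0, 0.6], [0.6, 1.0]])
    eng = make_continuous_engine(yobs=np.zeros((1, 2)),
                                 X=[np.zeros((1, 1)), np.zeros((1, 1))],
                                 lam_fixed=[1.0, 1.0], psi=psi)
    eng.data.mask[:] = False
    rng = np.random.default_rng(4)
    state = eng.init_state(rng)
    out = np.empty((30_000, 2))
    for k in range(out.shape[0]):
        eng.sample_factors(state, rng)
        out[k] = state.eta[0]
    assert np.allclose(out.mean(axis=0), 0.0, atol=0.03)
    assert np.allclose(np.cov(out.T), psi, atol=0.03)


def test_factor_conditional_shrinks_toward_correlated_factor():
    """With corr 0.9 and factor 1 measured precisely, factor 2's mean tracks
    0.9 x factor 1 (bivariate-normal conditional)."""
    psi = np.array([[1.0, 0.9], [0.9, 1.0]])
    lam = 20.0                                    # near-exact observation
    yobs = np.array([[lam * 1.5, 0.0]])
    data_mask = np.array([[True, False]])
    eng = make_continuous_engine(yobs=yobs, X=[np.zeros((1, 1)), np.zeros((1, 1))],
                                 lam_fixed=[lam, 1.0], psi=psi)
    eng.data.mask[:] = data_mask
    rng = np.random.default_rng(5)
    state = eng.init_state(rng)
    out = np.empty((20_000, 2))
    for k in range(out.shape[0]):
        eng.sample_factors(state, rng)
        out[k] = state.eta[0]
    assert abs(out[:, 0].mean() - 1.5) < 0.01
    assert abs(out[:, 1].mean() - 0.9 * out[:, 0].mean()) < 0.02


# ----------------------------------------------------------------------
# loading update
# ----------------------------------------------------------------------
def _tiny_domain_engine(n=120, seed=0):
    truth = gv.default_truth()
    cohort = gv.generate_cohort(truth, n, seed=seed)
    model = gv.InvestmentModel(cohort.table)
    return build_engine(model.spec, model.design)


def test_marker_loading_fixed_through_sweeps():
    """The marker loading is exactly 1 after any number of updates."""
    eng = _tiny_domain_engine()
    rng = np.random.default_rng(6)
    state = eng.init_state(rng)
    marker_cols = np.flatnonzero(eng.data.lam_group < 0)
    for _ in range(200):
        eng.sweep(state, rng)
    assert np.all(state.lam[marker_cols] == 1.0)


def test_loading_prior_limit_with_no_data():
    """A free loading with zero observed cells is drawn from its N(0,5)."""
    eng = _tiny_domain_engine()
    rng = np.random.default_rng(7)
    state = eng.init_state(rng)
    eng.data.mask[:] = False
    draws = np.empty(20_000)
    for k in range(draws.size):
        eng.sample_loadings(state, rng)
        draws[k] = state.lam_g[0]
    assert abs(draws.mean()) < 0.06
    assert abs(draws.var() - 5.0) < 0.15


def test_loading_posterior_matches_least_squares():
    """With eta known and diffuse-ish prior, the loading's posterior mean
    approaches the least-squares slope of y* on eta."""
    rng = np.random.default_rng(8)
    n = 4000
    eta = rng.standard_normal(n)
    lam_true = 0.7
    y = lam_true * eta + rng.standard_normal(n)
    data = EngineData(
        codes=np.zeros((n, 1), dtype=np.int64),
        mask=np.ones((n, 1), dtype=bool),
        item_factor=np.zeros(1, dtype=np.int64),
        item_ncat=np.zeros(1, dtype=np.int64),
        lam_group=np.array([0], dtype=np.int64),
        lam_fixed=np.zeros(1),
        tau_group=np.array([-1], dtype=np.int64),
        X=[np.zeros((n, 1))],
        yobs=y.reshape(-1, 1),
        lam_group_names=["free"],
    )
    eng = GibbsEngine(data, EnginePriors(), sample_psi=False,
                      psi_fixed=np.array([[1.0]]))
    state = eng.init_state(rng)
    state.eta[:, 0] = eta
    draws = np.empty(4000)
    for k in range(draws.size):
        eng.sample_loadings(state, rng)
        draws[k] = state.lam_g[0]
    ols = float(eta @ y / (eta @ eta))
    assert abs(draws.mean() - ols) < 0.02


# ----------------------------------------------------------------------
# threshold update
# ----------------------------------------------------------------------
def test_thresholds_strictly_increasing_through_sweeps():
    eng = _tiny_domain_engine(seed=1)
    rng = np.random.default_rng(9)
    state = eng.init_state(rng)
    for _ in range(150):
        eng.sweep(state, rng)
        for sl in eng._tau_slices:
            tau = state.tau_flat[sl]
            assert np.all(np.diff(tau) > 0)


def test_threshold_fallback_with_empty_neighbor_categories():
    """With no observations at all, interior cuts come from the N(0,1) prior
    truncated to the neighbouring thresholds."""
    eng = _tiny_domain_engine(seed=2)
    rng = np.random.default_rng(10)
    state = eng.init_state(rng)
    eng.data.mask[:] = False
    for _ in range(100):
        eng.sample_thresholds(state, rng)
        for sl in eng._tau_slices:
            assert np.all(np.diff(state.tau_flat[sl]) > 0)


# ----------------------------------------------------------------------
# structural update
# ----------------------------------------------------------------------
def test_structural_prior_limit_no_rows():
    """n = 0: the coefficient block is drawn from its N(0, 100^2) prior."""
    eng = make_continuous_engine(yobs=np.zeros((0, 1)), X=np.zeros((0, 2)),
                                 lam_fixed=[1.0], psi=[[1.0]])
    rng = np.random.default_rng(11)
    state = eng.init_state(rng)
    out = np.empty((3000, 2))
    for k in range(out.shape[0]):
        eng.sample_structural(state, rng)
        out[k] = state.beta
    assert abs(out.std() - 100.0) < 5.0
    assert abs(out.mean()) < 6.0


def test_structural_posterior_matches_gls_oracle():
    """Known eta, Psi = I: posterior mean equals equation-wise least squares."""
    rng = np.random.default_rng(12)
    n = 2000
    X1 = np.column_stack([np.ones(n), rng.standard_normal(n)])
    X2 = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    b1, b2 = np.array([0.3, -0.5]), np.array([-0.2, 0.4])
    eta = np.column_stack([X1 @ b1, X2 @ b2]) + rng.standard_normal((n, 2))
    eng = make_continuous_engine(yobs=np.zeros((n, 2)), X=[X1, X2],
                                 lam_fixed=[1.0, 1.0], psi=np.eye(2))
    eng.data.mask[:] = False
    rng2 = np.random.default_rng(13)
    state = eng.init_state(rng2)
    state.eta[:] = eta
    out = np.empty((4000, 4))
    for k in range(out.shape[0]):
        eng.sample_structural(state, rng2)
        out[k] = state.beta
    ols1 = np.linalg.lstsq(X1, eta[:, 0], rcond=None)[0]
    ols2 = np.linalg.lstsq(X2, eta[:, 1], rcond=None)[0]
    assert np.allclose(out.mean(axis=0), np.concatenate([ols1, ols2]), atol=0.02)


def test_reference_intercept_is_structurally_zero(default_spec):
    """The reference type has no intercept parameter at all (fixed 0)."""
    eng = _tiny_domain_engine()
    assert "alpha[MGM]" not in eng.param_names
    assert {"alpha[MGF]", "alpha[PGM]", "alpha[PGF]"} <= set(eng.param_names)


# ----------------------------------------------------------------------
# covariance update
# ----------------------------------------------------------------------
def test_covariance_draws_symmetric_positive_definite():
    eng = _tiny_domain_engine(seed=3)
    rng = np.random.default_rng(14)
    state = eng.init_state(rng)
    for _ in range(50):
        eng.sweep(state, rng)
        assert np.array_equal(state.Psi, state.Psi.T)
        assert np.linalg.eigvalsh(state.Psi).min() > 0


def test_covariance_concentrates_at_residual_covariance():
    """Large n with known residuals: draws concentrate at the empirical
    residual covariance (inverse-Wishart posterior mean)."""
    rng = np.random.default_rng(15)
    n = 6000
    true = np.array([[1.0, 0.5], [0.5, 2.0]])
    resid = rng.multivariate_normal(np.zeros(2), true, size=n)
    eng = make_continuous_engine(yobs=np.zeros((n, 2)),
                                 X=[np.zeros((n, 1)), np.zeros((n, 1))],
                                 lam_fixed=[1.0, 1.0], psi=np.eye(2))
    eng.sample_psi = True
    eng.data.mask[:] = False
    state = eng.init_state(rng)
    state.eta[:] = resid
    state.beta[:] = 0.0
    out = np.empty((800, 2, 2))
    for k in range(out.shape[0]):
        eng.sample_covariance(state, rng)
        out[k] = state.Psi
    emp = resid.T @ resid / n
    assert np.allclose(out.mean(axis=0), emp, atol=0.08)


# ----------------------------------------------------------------------
# chain orchestration
# ----------------------------------------------------------------------
def test_retained_draw_arithmetic():
    assert ChainConfig().n_retained == 3000
    cfg = ChainConfig(n_chains=1, iterations=100, burnin=40, thin=7, seed=0)
    eng = _tiny_domain_engine()
    cd = eng.run_chain(cfg, 0)
    assert cd.draws.shape[0] == (100 - 40) // 7


def test_chains_are_seed_deterministic():
    eng = _tiny_domain_engine()
    cfg = ChainConfig(n_chains=1, iterations=120, burnin=40, thin=2, seed=5)
    a = eng.run_chain(cfg, 0).draws
    b = eng.run_chain(cfg, 0).draws
    assert np.array_equal(a, b)
    c = eng.run_chain(cfg, 1).draws
    assert not np.array_equal(a, c)


def test_run_chains_structure():
    eng = _tiny_domain_engine()
    cfg = ChainConfig(n_chains=3, iterations=60, burnin=20, thin=2, seed=1)
    pd_ = eng.run_chains(cfg)
    assert pd_.draws.shape[0] == 3
    assert pd_.draws.shape[2] == len(eng.param_names)


def test_retain_latent_toggle():
    """Latent scores and augmented responses are retained only on request."""
    eng = _tiny_domain_engine(n=60, seed=6)
    cfg = ChainConfig(n_chains=1, iterations=40, burnin=20, thin=2, seed=2)
    plain = eng.run_chain(cfg, 0)
    assert plain.eta is None and plain.ystar is None
    kept = eng.run_chain(cfg, 0, retain_latent=True)
    n_keep = (40 - 20) // 2
    assert kept.eta.shape == (n_keep, eng.data.n, 4)
    assert kept.ystar.shape == (n_keep, eng.data.n, 16)
    # recorded named draws are unaffected by the toggle's code path
    assert kept.draws.shape == plain.draws.shape


def test_fused_and_stepwise_paths_agree():
    """The compiled fused sweep and the step-wise driver target the same
    posterior: summary statistics agree within Monte-Carlo error."""
    eng = _tiny_domain_engine(n=150, seed=4)
    cfg = ChainConfig(n_chains=1, iterations=2500, burnin=500, thin=2, seed=3)
    a = eng.run_chain(cfg, 0, fused=True).draws
    b = eng.run_chain(cfg, 0, fused=False).draws
    names = eng.param_names
    bidx = [i for i, nm in enumerate(names)
            if nm.startswith("beta[") or nm.startswith("alpha[")]
    gap = np.abs(a[:, bidx].mean(axis=0) - b[:, bidx].mean(axis=0))
    assert gap.max() < 0.15


def test_invariants_on_every_retained_draw(small_fit):
    """Every retained draw satisfies: thresholds strictly increasing, Psi
    symmetric PD, fixed parameters untouched."""
    model, res = small_fit
    names = res.draws.names
    # thresholds increasing, per item
    for item, K in [("Q15", 4), ("Q26", 4), ("Q27", 4), ("Q38", 3)]:
        cols = [names.index(f"tau[{item},{k+1}]") for k in range(K - 1)]
        tau = res.draws.draws[:, :, cols]
        assert np.all(np.diff(tau, axis=2) > 0)
    # Psi PD per draw
    G = 4
    iu = np.triu_indices(G)
    psi_cols = [names.index(n) for n in names if n.startswith("psi[")]
    flat = res.draws.draws[:, :, psi_cols].reshape(-1, len(psi_cols))
    for row in flat[::7]:
        m = np.zeros((G, G))
        m[iu] = row
        m = m + m.T - np.diag(np.diag(m))
        assert np.linalg.eigvalsh(m).min() > 0
    # no marker loading or reference intercept is ever sampled
    assert not any(n.startswith("lambda[Q38") for n in names)
    assert "alpha[MGM]" not in names
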