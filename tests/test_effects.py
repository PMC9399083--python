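"""Probit marginal effects and the phantom sensitivity machinery."""

import numpy as np
import pandas as pd
import pytest

import ginvest as gv
from ginvest.effects import (
    Scenario,
    add_phantom,
    category_probabilities,
    marginal_effect_table,
    within_lineage_coef_names,
)
from ginvest.spec import PhantomSpec


# ----------------------------------------------------------------------
# category probabilities
# ----------------------------------------------------------------------
def test_category_probabilities_symmetry():
    assert np.allclose(category_probabilities([0.0], 0.0, 1.0), [0.5, 0.5])


def test_category_probabilities_standard_normal_cells():
    got = category_probabilities([-1.0, 1.0], 0.0, 1.0)
    assert np.allclose(got, [0.158655, 0.682689, 0.158655], atol=1e-5)


def test_category_probabilities_extreme_predictor():
    got = category_probabilities([-1.0, 0.0, 1.0], 10.0, 1.0)
    assert got[-1] > 0.999999


def test_category_probabilities_sum_to_one():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tau = np.sort(rng.standard_normal(3))
        if np.any(np.diff(tau) <= 0):
            continue
        p = category_probabilities(tau, rng.standard_normal(), rng.gamma(2.0))
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()


def test_category_probabilities_translation_equivariance():
    tau = np.array([-0.5, 0.3, 1.1])
    a = category_probabilities(tau, 0.4, 1.3)
    b = category_probabilities(tau + 2.0, 0.4 + 2.0, 1.3)
    assert np.allclose(a, b)


def test_category_probabilities_rejects_bad_input():
    with pytest.raises(ValueError):
        category_probabilities([1.0, 0.0], 0.0, 1.0)
    with pytest.raises(ValueError):
        category_probabilities([0.0], 0.0, 0.0)


# ----------------------------------------------------------------------
# marginal effect table
# ----------------------------------------------------------------------
def _fake_summary(beta_int=0.3):
    spec = gv.build_default_spec()
    rows = {}
    for g in gv.GRANDPARENT_TYPES:
        for pred in spec.structural.predictors[g]:
            rows[f"beta[{g}~{pred}]"] = 0.0
        rows[f"psi[{g},{g}]"] = 1.0
        if g != "MGM":
            rows[f"alpha[{g}]"] = 0.0
    rows["beta[MGM~MGF_alive]"] = beta_int
    rows["tau[Q38,1]"] = -0.6
    rows["tau[Q38,2]"] = 0.6
    return pd.DataFrame({"median": pd.Series(rows)})


def test_marginal_effect_null_coefficient(default_spec, small_cohort):
    design = gv.encode_design(small_cohort.table, default_spec)
    summ = _fake_summary(beta_int=0.0)
    tab = marginal_effect_table(summ, default_spec, design,
                                [Scenario("MGM", "MGF_alive")])
    p0 = tab[tab.value == 0].filter(like="P(").to_numpy()
    p1 = tab[tab.value == 1].filter(like="P(").to_numpy()
    assert np.allclose(p0, p1)


def test_marginal_effect_positive_coefficient_shifts_mass_up(default_spec, small_cohort):
    design = gv.encode_design(small_cohort.table, default_spec)
    tab = marginal_effect_table(_fake_summary(0.3), default_spec, design,
                                [Scenario("MGM", "MGF_alive")])
    bottom0 = tab.loc[tab.value == 0, "P(cat 1)"].iloc[0]
    bottom1 = tab.loc[tab.value == 1, "P(cat 1)"].iloc[0]
    top0 = tab.loc[tab.value == 0, "P(cat 3)"].iloc[0]
    top1 = tab.loc[tab.value == 1, "P(cat 3)"].iloc[0]
    assert bottom1 < bottom0 and top1 > top0
    sums = tab.filter(like="P(").sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_marginal_effect_unknown_predictor_rejected(default_spec, small_cohort):
    design = gv.encode_design(small_cohort.table, default_spec)
    with pytest.raises(ValueError):
        marginal_effect_table(_fake_summary(), default_spec, design,
                              [Scenario("MGM", "MGM_alive")])


def test_marginal_effect_posterior_propagation(small_fit):
    """Full-posterior propagation gives probabilities close to the
    evaluate-at-medians mode on a well-behaved fit."""
    _, res = small_fit
    at_median = res.marginal_effects()
    propagated = res.marginal_effects(propagate=True)
    a = at_median.filter(like="P(").to_numpy()
    b = propagated.filter(like="P(").to_numpy()
    assert np.allclose(a, b, atol=0.05)
    assert np.all((b >= 0) & (b <= 1))


# ----------------------------------------------------------------------
# phantoms
# ----------------------------------------------------------------------
def test_add_phantom_structural_counts(default_spec):
    ph = PhantomSpec(exposure_type="MGF", outcome_type="MGM", gamma=0.157)
    sp1 = add_phantom(default_spec, ph, multiplier=1.0)
    assert len(sp1.phantoms) == 1
    assert sp1.phantoms[0].gamma == pytest.approx(0.157)
    sp2 = add_phantom(sp1, ph, multiplier=2.0)
    assert len(sp2.phantoms) == 2
    assert sp2.phantoms[1].gamma == pytest.approx(0.314)
    assert len(default_spec.phantoms) == 0          # original untouched


def test_add_phantom_rejects_between_lineage(default_spec):
    with pytest.raises(ValueError):
        add_phantom(default_spec,
                    PhantomSpec(exposure_type="MGM", outcome_type="PGF", gamma=0.1))


def test_within_lineage_pairs():
    names = within_lineage_coef_names()
    assert set(names) == {"beta[MGM~MGF_alive]", "beta[MGF~MGM_alive]",
                          "beta[PGM~PGF_alive]", "beta[PGF~PGM_alive]"}


def test_zero_gamma_phantom_is_statistical_noop(default_spec, small_cohort):
    """A phantom with gamma = 0 leaves the stationary distribution unchanged:
    structural medians agree within Monte-Carlo error."""
    model = gv.InvestmentModel(small_cohort.table)
    cfg = gv.ChainConfig(n_chains=2, iterations=2000, burnin=800, thin=2, seed=19)
    base = gv.build_engine(model.spec, model.design).run_chains(cfg)
    sp = add_phantom(model.spec, PhantomSpec("MGF", "MGM", gamma=0.0))
    ph = gv.build_engine(sp, model.design).run_chains(cfg)
    for name in ["beta[MGM~MGF_alive]", "beta[PGM~MGM_alive]", "beta[PGF~PGM_alive]"]:
        a = np.median(base.pooled(name))
        b = np.median(ph.pooled(name))
        assert abs(a - b) < 0.12


def test_sensitivity_scan_base_column_matches_base_fit(default_spec, small_cohort):
    model = gv.InvestmentModel(small_cohort.table)
    cfg = gv.ChainConfig(n_chains=2, iterations=1200, burnin=500, thin=2, seed=23)
    res = model.fit(chain_config=cfg)
    sens = res.sensitivity(scan=gv.PhantomScan(multipliers=(1.0,)), chain_config=cfg)
    assert len(sens.table) == 12
    assert sens.gamma > 0
    for row in sens.table.itertuples():
        name = f"beta[{row.focal}~{row.predictor}]"
        assert row.base_median == pytest.approx(
            float(res.summary_frame.loc[name, "median"]))
    assert {"x1_median", "x1_hpd_lo", "x1_hpd_hi", "sign_unstable"} <= set(sens.table.columns)
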