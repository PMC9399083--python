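"""Synthetic cohort generator: survival draws, measurement structure,
missingness, and the published default truth."""

import numpy as np
import pytest
from scipy.special import ndtr

import ginvest as gv
from ginvest.spec import GRANDPARENT_TYPES


def _expected_alive_given_one_alive(p):
    """Exact post-rejection column means: P(alive_g)/P(at least one alive)."""
    p = np.asarray(p, dtype=float)
    return p / (1.0 - np.prod(1.0 - p))


def test_draw_survival_matches_conditional_means():
    """Column means match the >=1-alive conditional expectation at MC error."""
    p = [0.837, 0.688, 0.732, 0.571]
    n = 100_000
    alive = gv.draw_survival(n, p, seed=3)
    want = _expected_alive_given_one_alive(p)
    se = np.sqrt(np.array(p) * (1 - np.array(p)) / n)
    assert np.all(np.abs(alive.mean(axis=0) - want) < 4 * se + 1e-9)
    assert alive.sum(axis=1).min() >= 1


def test_draw_survival_degenerate_probabilities():
    assert np.all(gv.draw_survival(50, [1, 1, 1, 1], seed=0) == 1)
    m = gv.draw_survival(50, [1, 0, 0, 0], seed=0)
    assert np.all(m[:, 0] == 1) and np.all(m[:, 1:] == 0)


def test_draw_survival_argument_errors():
    with pytest.raises(ValueError):
        gv.draw_survival(10, [0, 0, 0, 0], seed=0)
    with pytest.raises(ValueError):
        gv.draw_survival(0, [0.5] * 4, seed=0)


def test_default_truth_published_values(truth):
    """Structural medians and latent correlations carry the reported values."""
    assert truth.beta["MGM"]["MGF_alive"] == pytest.approx(0.157)
    assert truth.beta["PGM"]["MGM_alive"] == pytest.approx(-0.207)
    assert truth.beta["PGF"]["MGM_alive"] == pytest.approx(-0.207)
    corr = np.asarray(truth.psi_corr)
    assert corr[2, 3] == pytest.approx(0.958)
    assert corr[0, 1] == pytest.approx(0.881)
    assert np.linalg.eigvalsh(truth.psi_matrix()).min() > 0
    assert [truth.alive_probs[g] for g in GRANDPARENT_TYPES] == [0.837, 0.688, 0.732, 0.571]


def test_age_distribution_matches_observed_moments(truth):
    """Realised ages reproduce the survey's observed mean/sd on 11-16."""
    c = gv.generate_cohort(truth, 50_000, seed=1)
    assert c.table.age.between(11, 16).all()
    assert abs(c.table.age.mean() - 13.39) < 0.03
    assert abs(c.table.age.std() - 1.41) < 0.03


def test_generate_cohort_is_seed_reproducible(truth):
    a = gv.generate_cohort(truth, 5, seed=42).table
    b = gv.generate_cohort(truth, 5, seed=42).table
    assert a.equals(b)


def test_dead_type_has_all_missing_responses():
    t = gv.default_truth()
    t.alive_probs["MGM"] = 0.0
    cohort = gv.generate_cohort(t, 200, seed=0)
    for item in ("Q15", "Q26", "Q27", "Q38"):
        assert cohort.table[f"{item}_MGM"].isna().all()


def test_missingness_follows_alive_and_nonresponse(truth):
    """P(response present) = 0 for deceased, 1 - nonresponse for living."""
    cohort = gv.generate_cohort(truth, 20_000, seed=5)
    alive = cohort.table[[f"{g}_alive" for g in GRANDPARENT_TYPES]].to_numpy()
    mask = cohort.response_mask
    for j, col in enumerate(gv.build_default_spec().column_names()):
        g = GRANDPARENT_TYPES.index(col.rsplit("_", 1)[1])
        a = alive[:, g].astype(bool)
        assert not mask[~a, j].any()
        rate = mask[a, j].mean()
        assert abs(rate - (1 - truth.nonresponse_rate)) < 0.01


def test_marker_category_frequencies_match_quadrature():
    """With beta=0 the marker's category mass follows Phi cuts on the
    underlying N(0, lambda^2 zeta + 1) scale (latent integrated exactly)."""
    t = gv.default_truth()
    for g in t.beta:
        t.beta[g] = {k: 0.0 for k in t.beta[g]}
    t.alive_probs = {g: 1.0 for g in t.alive_probs}
    t.nonresponse_rate = 0.0
    t.psi_corr = np.eye(4).tolist()
    cohort = gv.generate_cohort(t, 60_000, seed=9)
    tau = np.asarray(t.thresholds["Q38"])
    s = np.sqrt(1.0**2 * 1.0 + 1.0)
    cdf = np.concatenate([[0.0], ndtr(tau / s), [1.0]])
    want = np.diff(cdf)
    got = cohort.table["Q38_MGM"].value_counts(normalize=True).sort_index().to_numpy()
    assert np.allclose(got, want, atol=0.01)


def test_latent_correlations_match_psi():
    """Empirical correlations of the generated latent residuals match Psi."""
    t = gv.default_truth()
    for g in t.beta:
        t.beta[g] = {k: 0.0 for k in t.beta[g]}
    cohort = gv.generate_cohort(t, 100_000, seed=11)
    emp = np.corrcoef(cohort.eta.T)
    assert np.allclose(emp, np.asarray(t.psi_corr), atol=0.02)


def test_category_mass_monotone_in_threshold_shift():
    """Raising every threshold moves mass into the lowest category."""
    t1 = gv.default_truth()
    t2 = gv.default_truth()
    t2.thresholds = {k: [x + 0.5 for x in v] for k, v in t2.thresholds.items()}
    c1 = gv.generate_cohort(t1, 20_000, seed=13)
    c2 = gv.generate_cohort(t2, 20_000, seed=13)
    for col in ("Q15_MGM", "Q38_PGF", "Q27_MGF"):
        low1 = (c1.table[col] == 1).mean()
        low2 = (c2.table[col] == 1).mean()
        assert low2 > low1


def test_reverse_coded_item_emitted_raw(truth):
    """Q26 is written in raw orientation: harmonised = K + 1 - raw, so its
    correlation with the same grandparent's Q27 should be negative raw-side."""
    cohort = gv.generate_cohort(truth, 5_000, seed=17)
    sub = cohort.table[["Q26_MGM", "Q27_MGM"]].dropna().astype(float)
    assert sub.corr().iloc[0, 1] < 0


def test_spouse_survival_correlation_toggle():
    """The within-lineage survival copula induces positive spousal
    correlation when enabled and none when off (the default)."""
    t_on = gv.default_truth()
    t_on.survival_corr = 0.5
    c_on = gv.generate_cohort(t_on, 20_000, seed=3)
    c_off = gv.generate_cohort(gv.default_truth(), 20_000, seed=3)
    r_on = np.corrcoef(c_on.table["MGM_alive"], c_on.table["MGF_alive"])[0, 1]
    r_off = np.corrcoef(c_off.table["MGM_alive"], c_off.table["MGF_alive"])[0, 1]
    assert r_on > 0.15
    assert abs(r_off) < 0.05


def test_truth_yaml_round_trip(truth):
    again = gv.GeneratorTruth.from_yaml(truth.to_yaml())
    assert again.to_dict() == truth.to_dict()


def test_generate_cohort_rejects_bad_truth():
    t = gv.default_truth()
    t.thresholds["Q15"] = [1.0, 0.0, -1.0]
    with pytest.raises(ValueError):
        gv.generate_cohort(t, 10, seed=0)
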