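"""Synthetic grandchild cohorts with known ground truth.

Generates survey tables with the statistical structure the analysis assumes:
each grandchild has an age, four grandparent alive/dead flags, and — for
living grandparents only — four ordinal item responses per grandparent driven
by a latent "investment" score.  The generating parameter set is returned
alongside the table so parameter-recovery tests can score the fit.

Structural coefficients and latent correlations default to the published
point estimates of the study being emulated; loadings, thresholds and latent
error variances are NOT published and their defaults here are synthetic
plumbing values (flagged in the truth metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .spec import GRANDPARENT_TYPES, ITEM_ORDER, ITEM_CATEGORIES, MARKER_ITEM, REVERSE_CODED_ITEMS

#: Survival proportions of MGM, MGF, PGM, PGF in the emulated cohort.
DEFAULT_ALIVE_PROBS = {"MGM": 0.837, "MGF": 0.688, "PGM": 0.732, "PGF": 0.571}

#: Published structural medians (alive-flag effects); age slope is synthetic.
DEFAULT_BETA = {
    "MGM": {"MGF_alive": 0.157, "PGM_alive": 0.057, "PGF_alive": 0.059, "age": -0.05},
    "MGF": {"MGM_alive": -0.044, "PGM_alive": -0.033, "PGF_alive": 0.009, "age": -0.05},
    "PGM": {"MGM_alive": -0.207, "MGF_alive": -0.001, "PGF_alive": 0.058, "age": -0.05},
    "PGF": {"MGM_alive": -0.207, "MGF_alive": -0.025, "PGM_alive": 0.062, "age": -0.05},
}

#: Published latent correlations (within-lineage 0.881 / 0.958; cross-lineage
#: 0.263, 0.303, 0.219, 0.263).
DEFAULT_PSI_CORR = [
    [1.0, 0.881, 0.263, 0.219],
    [0.881, 1.0, 0.303, 0.263],
    [0.263, 0.303, 1.0, 0.958],
    [0.219, 0.263, 0.958, 1.0],
]


@dataclass
class PhantomPath:
    """A generating within-lineage confounder: standard-normal latent with a
    linear path ``gamma_x`` into the exposure's survival probability and
    ``gamma_y`` into the outcome factor's latent mean."""

    exposure_type: str
    outcome_type: str
    gamma_x: float
    gamma_y: float


@dataclass
class GeneratorTruth:
    """Complete generating parameter set for a synthetic cohort."""

    alive_probs: dict = field(default_factory=lambda: dict(DEFAULT_ALIVE_PROBS))
    age_mean: float = 13.39
    age_sd: float = 1.41
    age_min: float = 11.0
    age_max: float = 16.0
    round_age: bool = False
    beta: dict = field(default_factory=lambda: {g: dict(d) for g, d in DEFAULT_BETA.items()})
    alpha: dict = field(default_factory=lambda: {g: 0.0 for g in GRANDPARENT_TYPES})
    #: loading per (item, type); marker fixed at 1, others default 0.9 (synthetic)
    loadings: dict = field(default_factory=lambda: {
        item: {g: (1.0 if item == MARKER_ITEM else 0.9) for g in GRANDPARENT_TYPES}
        for item in ITEM_ORDER
    })
    #: shared thresholds per item (synthetic plumbing values)
    thresholds: dict = field(default_factory=lambda: {
        item: ([-0.6, 0.6] if ITEM_CATEGORIES[item] == 3 else [-1.0, 0.0, 1.0])
        for item in ITEM_ORDER
    })
    psi_corr: list = field(default_factory=lambda: [list(r) for r in DEFAULT_PSI_CORR])
    zeta_var: dict = field(default_factory=lambda: {g: 1.0 for g in GRANDPARENT_TYPES})
    nonresponse_rate: float = 0.05
    survival_corr: float = 0.0          # within-lineage shared survival latent, off
    phantom_paths: list = field(default_factory=list)
    #: loadings/thresholds/zeta defaults are invented plumbing, not study values
    synthetic_measurement_defaults: bool = True

    # ------------------------------------------------------------------
    def psi_matrix(self) -> np.ndarray:
        """Latent error covariance: correlations scaled by zeta variances."""
        corr = np.asarray(self.psi_corr, dtype=float)
        sd = np.sqrt(np.array([self.zeta_var[g] for g in GRANDPARENT_TYPES]))
        return corr * np.outer(sd, sd)

    def validate(self) -> None:
        psi = self.psi_matrix()
        if not np.allclose(psi, psi.T):
            raise ValueError("psi must be symmetric")
        if np.linalg.eigvalsh(psi).min() <= 0:
            raise ValueError("psi must be positive definite")
        for g, p in self.alive_probs.items():
            if not (0 <= p <= 1):
                raise ValueError(f"alive probability for {g} must be in [0, 1]")
        if all(p == 0 for p in self.alive_probs.values()):
            raise ValueError("at least one alive probability must be positive")
        for item, tau in self.thresholds.items():
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"thresholds for {item} must be strictly increasing")
        if not (0 <= self.nonresponse_rate < 1):
            raise ValueError("nonresponse rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "GeneratorTruth":
        d = dict(d)
        d["phantom_paths"] = [
            PhantomPath(**p) if isinstance(p, dict) else p
            for p in d.get("phantom_paths", [])
        ]
        return GeneratorTruth(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "GeneratorTruth":
        return GeneratorTruth.from_dict(yaml.safe_load(text))


@dataclass
class CohortData:
    """A generated survey table plus oracle internals for recovery scoring."""

    table: pd.DataFrame
    response_mask: np.ndarray       # (n, n_items*4) True where a response exists
    eta: np.ndarray                 # (n, 4) latent investment scores (oracle)
    truth: GeneratorTruth


def default_truth() -> GeneratorTruth:
    """Truth populated with the published structural medians and latent
    correlations; measurement defaults are synthetic."""
    t = GeneratorTruth()
    t.validate()
    return t


def draw_survival(
    n: int,
    alive_probs,
    seed=None,
    survival_corr: float = 0.0,
) -> np.ndarray:
    """Draw an (n, 4) matrix of alive flags, rejecting all-dead rows.

    ``alive_probs`` is a mapping or length-4 sequence in MGM/MGF/PGM/PGF
    order.  Draws are independent Bernoulli per cell unless
    ``survival_corr`` > 0, in which case a shared within-lineage latent
    induces a positive survival correlation between spouses (Gaussian copula).
    Rows where all four grandparents are dead are redrawn so every grandchild
    has at least one living grandparent (the study's inclusion rule); this
    rejection shifts marginal alive proportions slightly upward.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(alive_probs, dict):
        p = np.array([alive_probs[g] for g in GRANDPARENT_TYPES], dtype=float)
    else:
        p = np.asarray(alive_probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("alive probabilities must lie in [0, 1]")
    if np.all(p == 0):
        raise ValueError("at least one alive probability must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _draw(m: int) -> np.ndarray:
        if survival_corr > 0:
            # Gaussian copula: spouses share a lineage latent with weight rho.
            rho = float(survival_corr)
            shared = rng.standard_normal((m, 2))          # maternal, paternal
            own = rng.standard_normal((m, 4))
            lineage_idx = np.array([0, 0, 1, 1])
            z = np.sqrt(rho) * shared[:, lineage_idx] + np.sqrt(1 - rho) * own
            return (z < stats.norm.ppf(p)).astype(np.int8)
        return (rng.random((m, 4)) < p).astype(np.int8)

    alive = _draw(n)
    bad = alive.sum(axis=1) == 0
    while bad.any():
        alive[bad] = _draw(int(bad.sum()))
        bad = alive.sum(axis=1) == 0
    return alive


from functools import lru_cache


@lru_cache(maxsize=32)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying normal (mu, sigma) whose [lo, hi]-truncation has the given
    OBSERVED mean and sd (the survey reports observed moments).  Falls back to
    (mean, sd) when no solution exists (sd too close to the uniform limit)."""
    from scipy import optimize

    def gap(p):
        mu, ls = p
        s = float(np.exp(ls))
        a, b = (lo - mu) / s, (hi - mu) / s
        d = stats.truncnorm(a, b, loc=mu, scale=s)
        return [d.mean() - mean, d.std() - sd]

    try:
        sol, _, ier, _ = optimize.fsolve(gap, [mean, np.log(sd)], full_output=True)
        if ier == 1:
            return float(sol[0]), float(np.exp(sol[1]))
    except Exception:
        pass
    return float(mean), float(sd)


def _draw_ages(truth: GeneratorTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, s = _truncnorm_params(truth.age_mean, truth.age_sd,
                              truth.age_min, truth.age_max)
    a = (truth.age_min - mu) / s
    b = (truth.age_max - mu) / s
    age = stats.truncnorm.rvs(a, b, loc=mu, scale=s, size=n, random_state=rng)
    if truth.round_age:
        age = np.clip(np.round(age), truth.age_min, truth.age_max)
    return age


def generate_cohort(truth: GeneratorTruth, n: int, seed=None) -> CohortData:
    """Generate ``n`` grandchild rows from ``truth``.

    Per row: alive flags and age are drawn; a 4-variate latent error
    zeta ~ N(0, Psi); latent investments eta_g = alpha_g + sum(beta * other
    alive flags) + beta_age * (age - mean) (+ confounder paths if configured);
    for each living grandparent and item, an underlying y* = lambda * eta +
    standard-normal noise is cut at the item's thresholds.  Deceased
    grandparents' items are all missing; living grandparents' responses are
    additionally thinned by the item nonresponse rate.  The reverse-coded item
    is emitted in its RAW (un-harmonised) orientation so the preprocessing
    step's reverse-scaling is exercised.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    truth.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = len(GRANDPARENT_TYPES)
    tidx = {g: i for i, g in enumerate(GRANDPARENT_TYPES)}

    # confounders: one standard-normal latent per configured path
    phantoms = [p if isinstance(p, PhantomPath) else PhantomPath(**p)
                for p in truth.phantom_paths]
    P = rng.standard_normal((n, len(phantoms))) if phantoms else np.zeros((n, 0))

    # survival: per-row probabilities when a confounder shifts them
    base_p = np.array([truth.alive_probs[g] for g in GRANDPARENT_TYPES])
    if np.all(base_p == 0):
        raise ValueError("at least one alive probability must be positive")
    probs = np.broadcast_to(base_p, (n, G)).copy()
    for k, ph in enumerate(phantoms):
        if ph.gamma_x:
            j = tidx[ph.exposure_type]
            probs[:, j] = np.clip(probs[:, j] + ph.gamma_x * P[:, k], 0.01, 0.99)
    def _draw_alive(p_rows: np.ndarray) -> np.ndarray:
        m = p_rows.shape[0]
        if truth.survival_corr > 0:
            # Gaussian copula: spouses share a lineage latent
            rho = float(truth.survival_corr)
            shared = rng.standard_normal((m, 2))
            own = rng.standard_normal((m, G))
            lineage_idx = np.array([0, 0, 1, 1])
            z = np.sqrt(rho) * shared[:, lineage_idx] + np.sqrt(1 - rho) * own
            return (z < stats.norm.ppf(np.clip(p_rows, 1e-12, 1 - 1e-12))).astype(np.int8)
        return (rng.random((m, G)) < p_rows).astype(np.int8)

    alive = _draw_alive(probs)
    bad = alive.sum(axis=1) == 0
    while bad.any():
        alive[bad] = _draw_alive(probs[bad])
        bad = alive.sum(axis=1) == 0

    age = _draw_ages(truth, n, rng)
    age_c = age - truth.age_mean

    # latent investments
    psi = truth.psi_matrix()
    zeta = rng.multivariate_normal(np.zeros(G), psi, size=n, method="cholesky")
    eta = np.empty((n, G))
    for g in GRANDPARENT_TYPES:
        gi = tidx[g]
        mu = np.full(n, truth.alpha[g])
        for pred, b in truth.beta[g].items():
            if pred == "age":
                mu += b * age_c
            else:
                mu += b * alive[:, tidx[pred.removesuffix("_alive")]]
        eta[:, gi] = mu + zeta[:, gi]
    for k, ph in enumerate(phantoms):
        if ph.gamma_y:
            eta[:, tidx[ph.outcome_type]] += ph.gamma_y * P[:, k]

    # ordinal responses
    J = len(ITEM_ORDER) * G
    codes = np.full((n, J), -1, dtype=np.int64)      # 0-based; -1 missing
    mask = np.zeros((n, J), dtype=bool)
    col = 0
    for item in ITEM_ORDER:
        tau = np.asarray(truth.thresholds[item], dtype=float)
        for g in GRANDPARENT_TYPES:
            lam = truth.loadings[item][g]
            ystar = lam * eta[:, tidx[g]] + rng.standard_normal(n)
            cat = np.searchsorted(tau, ystar)        # 0..n_cat-1
            present = alive[:, tidx[g]].astype(bool)
            if truth.nonresponse_rate > 0:
                present &= rng.random(n) >= truth.nonresponse_rate
            codes[present, col] = cat[present]
            mask[:, col] = present
            col += 1

    # assemble the table; reverse-coded items emitted in raw orientation
    data: dict = {"child_id": np.arange(1, n + 1)}
    data["age"] = age
    for g in GRANDPARENT_TYPES:
        data[f"{g}_alive"] = alive[:, tidx[g]]
    data["co_resident"] = np.zeros(n, dtype=np.int8)
    col = 0
    for item in ITEM_ORDER:
        ncat = ITEM_CATEGORIES[item]
        for g in GRANDPARENT_TYPES:
            vals = codes[:, col].astype(float) + 1.0          # 1-based categories
            if item in REVERSE_CODED_ITEMS:
                vals = ncat + 1 - vals
            vals[~mask[:, col]] = np.nan
            data[f"{item}_{g}"] = pd.array(vals, dtype="Int64")
            col += 1
    table = pd.DataFrame(data)
    return CohortData(table=table, response_mask=mask, eta=eta, truth=truth)


def write_cohort(cohort: CohortData, csv_path, truth_path=None) -> None:
    """Write the survey table as CSV (empty string = missing) and optionally
    the generating truth as a YAML sidecar for recovery scoring."""
    cohort.table.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(cohort.truth.to_yaml())
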