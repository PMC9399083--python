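"""Gibbs sampler for the ordinal-probit latent factor SUR model.

The generic model: G latent factors, each measured by ordinal items through a
probit threshold link (indicator residual variance fixed at 1), each factor
regressed on its own design matrix, with a full G x G latent error covariance.
Data augmentation follows the classic truncated-normal scheme: underlying
continuous responses y* are imputed cell-wise, after which every other full
conditional is conjugate.  Update order per sweep is fixed:
y* -> eta -> lambda -> tau -> (beta, alpha) -> Psi [-> phantoms].

Equality-constrained loadings and thresholds are sampled once per tied set by
pooling sufficient statistics across the tied cells.  Items may instead be
declared continuous, in which case augmentation is bypassed (y* is the
observed value) — the degenerate linear-Gaussian mode used by the exactness
checks.  Phantom confounders (indicator-less latents with fixed paths into an
exposure flag and a focal factor) are an optional extra update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from . import _kernels
from .spec import GRANDPARENT_TYPES, ChainConfig, ModelSpec
from .preprocess import DesignData

_INF = np.inf


# ----------------------------------------------------------------------
# engine-level data structures
# ----------------------------------------------------------------------
@dataclass
class EngineData:
    """Arrays describing one dataset for the generic sampler."""

    codes: np.ndarray           # (n, J) int64 0-based; -1 missing; unused if continuous
    mask: np.ndarray            # (n, J) bool
    item_factor: np.ndarray     # (J,) int64
    item_ncat: np.ndarray       # (J,) int64; 0 marks a continuous item
    lam_group: np.ndarray       # (J,) int64; -1 = fixed loading
    lam_fixed: np.ndarray       # (J,) float; value where fixed
    tau_group: np.ndarray       # (J,) int64; -1 = no thresholds
    X: list                     # per factor: (n, p_g) float design
    yobs: np.ndarray | None = None   # (n, J) float; continuous observations
    factor_names: list = field(default_factory=list)
    beta_names: list = field(default_factory=list)      # per factor: list of names
    lam_group_names: list = field(default_factory=list)
    tau_group_names: list = field(default_factory=list)  # per group: base label

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def J(self) -> int:
        return self.codes.shape[1]

    @property
    def G(self) -> int:
        return len(self.X)


@dataclass
class EnginePriors:
    beta_mean: float = 0.0
    beta_var: float = 100.0**2
    loading_mean: float = 0.0
    loading_var: float = 5.0
    threshold_mean: float = 0.0
    threshold_var: float = 1.0
    psi_df: float | None = None          # default: G + 1
    psi_scale: np.ndarray | None = None  # default: identity


@dataclass
class EnginePhantom:
    """Compiled phantom confounder: fixed-path latent into one exposure flag
    (via a linear or probit auxiliary equation) and one outcome factor."""

    exposure: np.ndarray      # (n,) float 0/1 observed flag
    outcome_factor: int
    gamma: float
    auxiliary: str = "linear"
    label: str = "phantom"


@dataclass
class ParameterState:
    """One full set of sampler unknowns (spec symbols in comments)."""

    lam: np.ndarray           # per-item loadings (lambda), constraints honoured
    lam_g: np.ndarray         # free loading value per tied group
    tau_flat: np.ndarray      # concatenated shared threshold vectors (tau)
    beta: np.ndarray          # stacked structural coefficients + intercepts (beta, alpha)
    Psi: np.ndarray           # latent error covariance (Psi; diagonal = zeta)
    Psi_inv: np.ndarray
    eta: np.ndarray           # (n, G) latent scores
    ystar: np.ndarray         # (n, J) augmented continuous responses
    phi: np.ndarray           # (n, K) phantom scores
    nu: np.ndarray            # (K,) phantom auxiliary intercepts
    sig2: np.ndarray          # (K,) phantom auxiliary residual variances
    astar: np.ndarray         # (n, K) augmented exposures (probit auxiliary only)


@dataclass
class ChainDraws:
    """Retained draws of one chain: (n_kept, n_params).

    ``eta``/``ystar`` hold per-iteration latent states only when the chain was
    run with ``retain_latent=True`` (memory-heavy; off by default)."""

    draws: np.ndarray
    names: list
    chain_id: int
    seed: int
    config: ChainConfig
    eta: np.ndarray | None = None        # (n_kept, n, G) if retained
    ystar: np.ndarray | None = None      # (n_kept, n, J) if retained


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws, per chain, for named parameters."""

    draws: np.ndarray         # (n_chains, n_kept, n_params)
    names: list
    config: ChainConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) draws of one parameter."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_dataframe(self):
        import pandas as pd

        C, T, P = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(C * T, P), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(C), T))
        df.insert(1, "draw", np.tile(np.arange(T), C))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


# ----------------------------------------------------------------------
# the sampler
# ----------------------------------------------------------------------
class GibbsEngine:
    """Full-conditional Gibbs sampler bound to one dataset.

    Parameters
    ----------
    data : EngineData
    priors : EnginePriors
    phantoms : list of EnginePhantom, optional
    sample_psi : bool
        If False, ``psi_fixed`` is held constant (used by exactness checks
        with known Psi).
    """

    def __init__(self, data: EngineData, priors: EnginePriors | None = None,
                 phantoms: list | None = None, sample_psi: bool = True,
                 psi_fixed: np.ndarray | None = None):
        self.data = data
        self.priors = priors or EnginePriors()
        self.phantoms = phantoms or []
        self.sample_psi = sample_psi
        G = data.G
        self.psi_fixed = np.asarray(psi_fixed, dtype=float) if psi_fixed is not None else None
        if self.priors.psi_df is None:
            self.priors.psi_df = G + 1.0
        if self.priors.psi_scale is None:
            self.priors.psi_scale = np.eye(G)

        # beta layout: one stacked vector with per-factor slices
        self._beta_slices = []
        p0 = 0
        for g in range(G):
            p = data.X[g].shape[1]
            self._beta_slices.append(slice(p0, p0 + p))
            p0 += p
        self._P = p0
        # precomputed cross-products for the SUR update
        self._XtX = [[data.X[g].T @ data.X[h] for h in range(G)] for g in range(G)]

        # tau layout: flat vector with one slice per group
        self.n_tau_groups = int(data.tau_group.max()) + 1 if data.tau_group.size and data.tau_group.max() >= 0 else 0
        self._tau_slices = []
        self._tau_group_ncat = []
        start = 0
        for t in range(self.n_tau_groups):
            cols = np.flatnonzero(data.tau_group == t)
            K = int(data.item_ncat[cols[0]])
            self._tau_group_ncat.append(K)
            self._tau_slices.append(slice(start, start + K - 1))
            start += K - 1
        self._T = start
        # per-item pointer into tau_flat (kernel convention)
        self._item_tau_start = np.zeros(data.J, dtype=np.int64)
        for j in range(data.J):
            t = data.tau_group[j]
            self._item_tau_start[j] = self._tau_slices[t].start if t >= 0 else 0

        self.n_lam_groups = int(data.lam_group.max()) + 1 if data.lam_group.size and data.lam_group.max() >= 0 else 0

        # flattened layout for the fused chain kernel
        Xall = np.concatenate([data.X[g] for g in range(G)], axis=1) if self._P else np.empty((data.n, 0))
        self._XallT = np.ascontiguousarray(Xall.T)
        self._col_factor = np.concatenate(
            [np.full(data.X[g].shape[1], g, dtype=np.int64) for g in range(G)]
        ) if self._P else np.empty(0, dtype=np.int64)
        self._Cfull = Xall.T @ Xall
        self._tg_start = np.array([s.start for s in self._tau_slices], dtype=np.int64)
        self._tg_ncat = np.array(self._tau_group_ncat, dtype=np.int64)
        cols_per_group = [np.flatnonzero(data.tau_group == t) for t in range(self.n_tau_groups)]
        self._tg_cols = (np.concatenate(cols_per_group).astype(np.int64)
                         if cols_per_group else np.empty(0, dtype=np.int64))
        self._tg_ptr = np.zeros(self.n_tau_groups + 1, dtype=np.int64)
        for t, c in enumerate(cols_per_group):
            self._tg_ptr[t + 1] = self._tg_ptr[t] + c.size

        self.param_names = self._build_names()

    # -- naming --------------------------------------------------------
    def _build_names(self) -> list:
        d = self.data
        names: list[str] = []
        for g in range(d.G):
            fname = d.factor_names[g] if d.factor_names else f"f{g}"
            bn = d.beta_names[g] if d.beta_names else [f"x{k}" for k in range(d.X[g].shape[1])]
            for b in bn:
                if b == "intercept":
                    names.append(f"alpha[{fname}]")
                else:
                    names.append(f"beta[{fname}~{b}]")
        for l in range(self.n_lam_groups):
            lbl = d.lam_group_names[l] if d.lam_group_names else f"g{l}"
            names.append(f"lambda[{lbl}]")
        for t in range(self.n_tau_groups):
            lbl = d.tau_group_names[t] if d.tau_group_names else f"t{t}"
            for k in range(self._tau_group_ncat[t] - 1):
                names.append(f"tau[{lbl},{k + 1}]")
        fns = d.factor_names or [f"f{g}" for g in range(d.G)]
        for a in range(d.G):
            for b in range(a, d.G):
                names.append(f"psi[{fns[a]},{fns[b]}]")
        for k, ph in enumerate(self.phantoms):
            names.append(f"phantom_nu[{ph.label}]")
            names.append(f"phantom_sig2[{ph.label}]")
        return names

    # -- state initialisation -----------------------------------------
    def init_state(self, rng: np.random.Generator) -> ParameterState:
        d = self.data
        n, J, G = d.n, d.J, d.G
        lam_g = np.ones(self.n_lam_groups)
        lam = self._expand_lam(lam_g)
        # thresholds from pooled marginal category proportions (inverse-normal cuts)
        tau_flat = np.zeros(self._T)
        for t in range(self.n_tau_groups):
            cols = np.flatnonzero(d.tau_group == t)
            K = self._tau_group_ncat[t]
            counts = np.zeros(K)
            for j in cols:
                obs = d.codes[d.mask[:, j], j]
                counts += np.bincount(obs, minlength=K)
            if counts.sum() == 0:
                cuts = np.linspace(-1, 1, K - 1) if K > 2 else np.zeros(1)
            else:
                cum = np.cumsum(counts)[:-1] / counts.sum()
                cum = np.clip(cum, 1e-3, 1 - 1e-3)
                cum = np.maximum.accumulate(cum + 1e-6 * np.arange(K - 1))
                cuts = np.array([_kernels.ndtri(c) for c in cum])
            tau_flat[self._tau_slices[t]] = cuts
        beta = np.zeros(self._P)
        Psi = self.psi_fixed.copy() if self.psi_fixed is not None else np.eye(G)
        Psi_inv = np.linalg.inv(Psi)
        eta = np.zeros((n, G))
        ystar = np.zeros((n, J))
        if d.yobs is not None:
            cont = d.item_ncat == 0
            ystar[:, cont] = d.yobs[:, cont]
        K = len(self.phantoms)
        phi = np.zeros((n, K))
        nu = np.zeros(K)
        sig2 = np.ones(K)
        for k, ph in enumerate(self.phantoms):
            nu[k] = float(ph.exposure.mean())
            v = float(ph.exposure.var())
            sig2[k] = v if v > 1e-6 else 1.0
        astar = np.zeros((n, K))
        state = ParameterState(lam=lam, lam_g=lam_g, tau_flat=tau_flat, beta=beta,
                               Psi=Psi, Psi_inv=Psi_inv, eta=eta, ystar=ystar,
                               phi=phi, nu=nu, sig2=sig2, astar=astar)
        self.sample_latent_responses(state, rng)
        return state

    def _expand_lam(self, lam_g: np.ndarray) -> np.ndarray:
        d = self.data
        lam = d.lam_fixed.astype(float).copy()
        free = d.lam_group >= 0
        if free.any():
            lam[free] = lam_g[d.lam_group[free]]
        return lam

    # -- structural mean ----------------------------------------------
    def structural_mean(self, state: ParameterState) -> np.ndarray:
        d = self.data
        mu = np.empty((d.n, d.G))
        for g in range(d.G):
            Xg = d.X[g]
            mu[:, g] = Xg @ state.beta[self._beta_slices[g]] if Xg.shape[1] else 0.0
        for k, ph in enumerate(self.phantoms):
            mu[:, ph.outcome_factor] += ph.gamma * state.phi[:, k]
        return mu

    # -- full-conditional updates -------------------------------------
    def sample_latent_responses(self, state: ParameterState, rng) -> None:
        """Redraw y* at observed ordinal cells (truncated normal); masked
        cells and continuous items untouched."""
        d = self.data
        U = rng.random((d.n, d.J))
        _kernels.update_ystar(state.ystar, d.codes, d.mask, state.lam, state.eta,
                              d.item_factor, d.item_ncat, state.tau_flat,
                              self._item_tau_start, U)

    def sample_factors(self, state: ParameterState, rng) -> None:
        """Draw each row's latent vector from its exact MVN full conditional;
        rows with no observed indicators revert toward the structural law."""
        d = self.data
        Z = rng.standard_normal((d.n, d.G))
        mu = self.structural_mean(state)
        _kernels.update_eta(state.eta, state.ystar, d.mask, state.lam,
                            d.item_factor, state.Psi_inv, mu, Z)

    def sample_loadings(self, state: ParameterState, rng) -> None:
        """Conjugate normal update per free loading group, pooling sufficient
        statistics across tied cells; fixed (marker) loadings never move."""
        if self.n_lam_groups == 0:
            return
        d = self.data
        pr = self.priors
        eta_cols = state.eta[:, d.item_factor]           # (n, J)
        W = d.mask * eta_cols
        shh = np.einsum("ij,ij->j", W, eta_cols)
        shy = np.einsum("ij,ij->j", W, state.ystar)
        free = d.lam_group >= 0
        gidx = d.lam_group[free]
        shh_g = np.bincount(gidx, weights=shh[free], minlength=self.n_lam_groups)
        shy_g = np.bincount(gidx, weights=shy[free], minlength=self.n_lam_groups)
        prec = 1.0 / pr.loading_var + shh_g
        mean = (pr.loading_mean / pr.loading_var + shy_g) / prec
        state.lam_g = mean + rng.standard_normal(self.n_lam_groups) / np.sqrt(prec)
        state.lam = self._expand_lam(state.lam_g)

    def sample_thresholds(self, state: ParameterState, rng) -> None:
        """Truncated-prior update of each interior threshold, pooled over tied
        cells; empty categories fall back to the neighbouring thresholds."""
        d = self.data
        pr = self.priors
        sd = math.sqrt(pr.threshold_var)
        for t in range(self.n_tau_groups):
            cols = np.flatnonzero(d.tau_group == t)
            K = self._tau_group_ncat[t]
            sl = self._tau_slices[t]
            tau = state.tau_flat[sl]
            maxs, mins = _kernels.category_extrema(state.ystar, d.codes, d.mask,
                                                   cols.astype(np.int64), K)
            for m in range(K - 1):
                lo = maxs[m]
                hi = mins[m + 1]
                if m > 0:
                    lo = max(lo, tau[m - 1])
                if m < K - 2:
                    hi = min(hi, tau[m + 1])
                if lo >= hi:
                    raise FloatingPointError(
                        f"inverted threshold bounds ({lo}, {hi}) in group {t}")
                a = (lo - pr.threshold_mean) / sd
                b = (hi - pr.threshold_mean) / sd
                tau[m] = pr.threshold_mean + sd * _kernels.truncnorm_draw(
                    0.0, a, b, float(rng.random()))
            state.tau_flat[sl] = tau

    def sample_structural(self, state: ParameterState, rng) -> None:
        """Joint conjugate MVN draw of the stacked coefficient block
        (seemingly-unrelated-regressions across the factor equations)."""
        d = self.data
        pr = self.priors
        G = d.G
        if self._P == 0:
            return
        target = state.eta.copy()
        for k, ph in enumerate(self.phantoms):
            target[:, ph.outcome_factor] -= ph.gamma * state.phi[:, k]
        M = np.zeros((self._P, self._P))
        rhs = np.full(self._P, pr.beta_mean / pr.beta_var)
        for g in range(G):
            Tg = d.X[g].T @ target if d.X[g].shape[1] else None
            for h in range(G):
                w = state.Psi_inv[g, h]
                M[self._beta_slices[g], self._beta_slices[h]] += w * self._XtX[g][h]
            if Tg is not None:
                rhs[self._beta_slices[g]] += Tg @ state.Psi_inv[g]
        M[np.diag_indices_from(M)] += 1.0 / pr.beta_var
        try:
            c, low = cho_factor(M, lower=True)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"structural design collinear: {e}") from e
        mean = cho_solve((c, low), rhs)
        z = rng.standard_normal(self._P)
        state.beta = mean + solve_triangular(c, z, lower=True, trans="T")

    def sample_covariance(self, state: ParameterState, rng) -> None:
        """Inverse-Wishart update of the latent error covariance."""
        if not self.sample_psi:
            return
        d = self.data
        pr = self.priors
        R = state.eta - self.structural_mean(state)
        S = pr.psi_scale + R.T @ R
        state.Psi = _draw_invwishart(rng, pr.psi_df + d.n, S)
        state.Psi_inv = np.linalg.inv(state.Psi)

    def sample_phantoms(self, state: ParameterState, rng) -> None:
        """Update phantom scores and their auxiliary-equation parameters."""
        d = self.data
        for k, ph in enumerate(self.phantoms):
            c = ph.gamma
            f = ph.outcome_factor
            # structural residual with this phantom's contribution removed
            mu = self.structural_mean(state)
            r = state.eta - mu
            r[:, f] += c * state.phi[:, k]
            proj = r @ state.Psi_inv[:, f]                # (n,)
            if ph.auxiliary == "probit":
                lin = state.nu[k] + c * state.phi[:, k]
                u = rng.random(d.n)
                pos = ph.exposure > 0.5
                a_ = np.where(pos, _vec_ndtr(-lin), np.full(d.n, 0.0))
                b_ = np.where(pos, np.ones(d.n), _vec_ndtr(-lin))
                # draw a* truncated to sign region
                p = np.where(pos, a_ + u * (1.0 - a_), u * b_)
                state.astar[:, k] = lin + _vec_ndtri(np.clip(p, 1e-15, 1 - 1e-15))
                a_resp = state.astar[:, k]
                s2 = 1.0
            else:
                a_resp = ph.exposure
                s2 = state.sig2[k]
            prec = 1.0 + c * c / s2 + c * c * state.Psi_inv[f, f]
            mean = (c * (a_resp - state.nu[k]) / s2 + c * proj) / prec
            state.phi[:, k] = mean + rng.standard_normal(d.n) / math.sqrt(prec)
            # auxiliary intercept (diffuse normal prior)
            resid = a_resp - c * state.phi[:, k]
            v = 1.0 / (d.n / s2 + 1.0 / self.priors.beta_var)
            state.nu[k] = v * resid.sum() / s2 + math.sqrt(v) * rng.standard_normal()
            if ph.auxiliary != "probit":
                ssr = float(np.sum((resid - state.nu[k]) ** 2))
                a_post = 0.001 + 0.5 * d.n
                b_post = 0.001 + 0.5 * ssr
                state.sig2[k] = b_post / rng.gamma(a_post)

    # -- orchestration -------------------------------------------------
    def sweep(self, state: ParameterState, rng) -> None:
        self.sample_latent_responses(state, rng)
        self.sample_factors(state, rng)
        self.sample_loadings(state, rng)
        self.sample_thresholds(state, rng)
        self.sample_structural(state, rng)
        self.sample_covariance(state, rng)
        if self.phantoms:
            self.sample_phantoms(state, rng)

    def record(self, state: ParameterState) -> np.ndarray:
        G = self.data.G
        iu = np.triu_indices(G)
        parts = [state.beta, state.lam_g, state.tau_flat, state.Psi[iu]]
        if self.phantoms:
            parts.append(np.column_stack([state.nu, state.sig2]).reshape(-1))
        return np.concatenate(parts)

    def run_chain(self, config: ChainConfig, chain_id: int = 0,
                  progress=None, fused: bool = True,
                  retain_latent: bool = False) -> ChainDraws:
        """Run one chain; fully reproducible from (config.seed, chain_id).

        The fused compiled sweep is used when available (probit-auxiliary
        phantoms, empty designs and ``retain_latent`` fall back to the
        step-wise driver, which targets the same stationary distribution)."""
        config.validate()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, chain_id]))
        state = self.init_state(rng)
        n_keep = config.n_retained
        out = np.empty((n_keep, len(self.param_names)))
        use_fused = (fused and self._P > 0 and not retain_latent
                     and all(ph.auxiliary != "probit" for ph in self.phantoms))
        if use_fused:
            d = self.data
            pr = self.priors
            K = len(self.phantoms)
            ph_exposure = (np.column_stack([ph.exposure for ph in self.phantoms])
                           if K else np.zeros((d.n, 0)))
            ph_outfac = np.array([ph.outcome_factor for ph in self.phantoms],
                                 dtype=np.int64)
            ph_gamma = np.array([ph.gamma for ph in self.phantoms], dtype=float)
            k = _kernels.run_chain_fused(
                rng, d.codes, d.mask, d.item_factor, d.item_ncat,
                self._item_tau_start, self._XallT, self._col_factor, self._Cfull,
                d.lam_group, self._tg_start, self._tg_ncat, self._tg_cols,
                self._tg_ptr,
                pr.beta_mean, pr.beta_var, pr.loading_mean, pr.loading_var,
                pr.threshold_mean, pr.threshold_var,
                float(pr.psi_df), np.asarray(pr.psi_scale, dtype=float),
                self.sample_psi,
                ph_exposure, ph_outfac, ph_gamma,
                state.ystar, state.eta, state.lam, state.lam_g, state.tau_flat,
                state.beta, state.Psi, state.Psi_inv, state.phi, state.nu,
                state.sig2,
                config.iterations, config.burnin, config.thin, out)
            if progress is not None:
                progress(chain_id, config.iterations, config.iterations)
            return ChainDraws(draws=out[:k], names=self.param_names,
                              chain_id=chain_id, seed=config.seed, config=config)
        eta_keep = np.empty((n_keep,) + state.eta.shape) if retain_latent else None
        ystar_keep = np.empty((n_keep,) + state.ystar.shape) if retain_latent else None
        k = 0
        for it in range(config.iterations):
            self.sweep(state, rng)
            if it >= config.burnin and (it - config.burnin) % config.thin == config.thin - 1:
                if k < n_keep:
                    out[k] = self.record(state)
                    if retain_latent:
                        eta_keep[k] = state.eta
                        ystar_keep[k] = state.ystar
                    k += 1
            if progress is not None and (it + 1) % max(1, config.iterations // 10) == 0:
                progress(chain_id, it + 1, config.iterations)
        return ChainDraws(draws=out[:k], names=self.param_names, chain_id=chain_id,
                          seed=config.seed, config=config,
                          eta=eta_keep[:k] if retain_latent else None,
                          ystar=ystar_keep[:k] if retain_latent else None)

    def run_chains(self, config: ChainConfig, progress=None) -> PosteriorDraws:
        """Run ``config.n_chains`` chains with distinct sub-seeds; results are
        independent of scheduling because each chain owns its RNG stream."""
        chains = [self.run_chain(config, cid, progress=progress)
                  for cid in range(config.n_chains)]
        n_keep = min(c.draws.shape[0] for c in chains)
        draws = np.stack([c.draws[:n_keep] for c in chains])
        return PosteriorDraws(draws=draws, names=self.param_names, config=config)


def _draw_invwishart(rng: np.random.Generator, df: float, S: np.ndarray) -> np.ndarray:
    """Psi ~ InvWishart(df, scale=S) via the Bartlett decomposition."""
    G = S.shape[0]
    # W ~ Wishart(df, S^{-1}); Psi = W^{-1}
    L = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((G, G))
    for i in range(G):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    F = L @ A
    Finv = solve_triangular(F, np.eye(G), lower=True)
    Psi = Finv.T @ Finv
    return 0.5 * (Psi + Psi.T)


def _vec_ndtr(x: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(x)


def _vec_ndtri(p: np.ndarray) -> np.ndarray:
    from scipy.special import ndtri

    return ndtri(p)


# ----------------------------------------------------------------------
# compilation from the domain spec
# ----------------------------------------------------------------------
def build_engine(spec: ModelSpec, design: DesignData,
                 priors: EnginePriors | None = None) -> GibbsEngine:
    """Compile the four-factor grandparental-investment model into the
    generic engine: item-major column layout, marker loadings fixed at 1,
    the non-invariant item's loading free per type, other loadings shared,
    thresholds shared per item, full 4x4 Psi, per-factor designs from
    ``design`` (reference type has no free intercept)."""
    G = len(GRANDPARENT_TYPES)
    J = len(spec.items) * G
    item_factor = np.empty(J, dtype=np.int64)
    item_ncat = np.empty(J, dtype=np.int64)
    lam_group = np.full(J, -1, dtype=np.int64)
    lam_fixed = np.zeros(J)
    tau_group = np.full(J, -1, dtype=np.int64)
    lam_names: list[str] = []
    tau_names: list[str] = []
    lam_gid: dict[str, int] = {}
    col = 0
    for it_idx, item in enumerate(spec.items):
        tau_names.append(item.name)
        for g_idx, g in enumerate(GRANDPARENT_TYPES):
            item_factor[col] = g_idx
            item_ncat[col] = item.n_categories
            tau_group[col] = it_idx
            if item.is_marker:
                lam_fixed[col] = 1.0
            elif item.name == spec.invariance.free_loading_item:
                key = f"{item.name},{g}"
                if key not in lam_gid:
                    lam_gid[key] = len(lam_names)
                    lam_names.append(key)
                lam_group[col] = lam_gid[key]
            else:
                if item.name not in lam_gid:
                    lam_gid[item.name] = len(lam_names)
                    lam_names.append(item.name)
                lam_group[col] = lam_gid[item.name]
            col += 1

    X = [design.X[g] for g in GRANDPARENT_TYPES]
    beta_names = [design.x_names[g] for g in GRANDPARENT_TYPES]

    if priors is None:
        priors = EnginePriors(
            beta_mean=spec.priors.beta_mean,
            beta_var=spec.priors.beta_var,
            loading_mean=spec.priors.loading_mean,
            loading_var=spec.priors.loading_var,
            threshold_mean=spec.priors.threshold_mean,
            threshold_var=spec.priors.threshold_var,
            psi_df=spec.priors.psi_df,
            psi_scale=spec.priors.psi_scale_diag * np.eye(G),
        )

    data = EngineData(
        codes=design.codes,
        mask=design.mask,
        item_factor=item_factor,
        item_ncat=item_ncat,
        lam_group=lam_group,
        lam_fixed=lam_fixed,
        tau_group=tau_group,
        X=X,
        factor_names=list(GRANDPARENT_TYPES),
        beta_names=beta_names,
        lam_group_names=lam_names,
        tau_group_names=tau_names,
    )

    gi = {g: i for i, g in enumerate(GRANDPARENT_TYPES)}
    phantoms = []
    for ph in spec.phantoms:
        ph.validate()
        phantoms.append(EnginePhantom(
            exposure=design.alive[:, gi[ph.exposure_type]].astype(float),
            outcome_factor=gi[ph.outcome_type],
            gamma=ph.gamma,
            auxiliary=ph.auxiliary,
            label=f"{ph.exposure_type}->{ph.outcome_type}",
        ))
    return GibbsEngine(data, priors, phantoms=phantoms)
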