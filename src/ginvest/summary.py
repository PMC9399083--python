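"""Posterior point/interval summaries and convergence diagnostics.

Reporting conventions follow the study being reproduced: posterior medians as
point estimates, 95% highest-posterior-density intervals, a one-tailed
posterior p (the mass on the opposite side of zero from the median), and the
Gelman–Rubin potential scale reduction factor computed from the retained
(thinned, post-burn-in) draws of multiple chains.
"""

from __future__ import annotations

import math
import re
import warnings

import numpy as np
import pandas as pd

from .engine import PosteriorDraws
from .spec import GRANDPARENT_TYPES

#: PSRF thresholds conventionally read as good convergence.
PSRF_STRICT = 1.1
PSRF_LENIENT = 1.2


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted draws holding ceil(mass*n)
    draws; ties broken by the lowest start."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    m = min(m, n)
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))          # first minimum = lowest start
    return float(x[k]), float(x[k + m - 1])


def one_tailed_p(draws) -> float:
    """Posterior mass strictly on the opposite side of zero from the median."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("need at least 1 draw")
    med = float(np.median(x))
    if med > 0:
        return float(np.mean(x < 0))
    if med < 0:
        return float(np.mean(x > 0))
    return 0.5


def psrf(chain_blocks) -> float:
    """Gelman–Rubin potential scale reduction factor.

    ``chain_blocks`` is a sequence of per-chain draw sequences of equal
    length.  Returns sqrt((((n-1)/n) W + B/n) / W) with W the mean
    within-chain variance and B the between-chain variance of chain means
    (times n).  NaN flags the degenerate W = 0 case.
    """
    chains = [np.asarray(c, dtype=float) for c in chain_blocks]
    if len(chains) < 2:
        raise ValueError("PSRF needs at least 2 chains")
    n = chains[0].size
    if n < 2 or any(c.size != n for c in chains):
        raise ValueError("PSRF needs equal-length chains with >= 2 draws each")
    W = float(np.mean([np.var(c, ddof=1) for c in chains]))
    means = np.array([c.mean() for c in chains])
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        return float("nan")
    return math.sqrt((((n - 1) / n) * W + B / n) / W)


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size of a (n_chains, n_draws) array (arviz)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(np.asarray(chains, dtype=float)))


def mcse_median(chains: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior median (arviz)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.mcse(np.asarray(chains, dtype=float), method="median"))


# ----------------------------------------------------------------------
def _correlation_draws(pdraws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Latent correlations computed per draw from the Psi draws (the
    nonlinear transform is applied before summarising, never after)."""
    psi_names = [n for n in pdraws.names if n.startswith("psi[")]
    if not psi_names:
        return {}
    pat = re.compile(r"psi\[(.+),(.+)\]")
    diag: dict[str, np.ndarray] = {}
    for n in psi_names:
        a, b = pat.match(n).groups()
        if a == b:
            diag[a] = pdraws.get(n)
    out: dict[str, np.ndarray] = {}
    for n in psi_names:
        a, b = pat.match(n).groups()
        if a != b and a in diag and b in diag:
            out[f"rho[{a},{b}]"] = pdraws.get(n) / np.sqrt(diag[a] * diag[b])
    return out


def _report_order(names: list[str]) -> list[str]:
    """Structural alive-flag rows first (focal blocks in MGM/MGF/PGM/PGF
    order, predictors in the same order), then age effects, intercepts,
    loadings, thresholds, Psi entries, correlations, phantom parameters."""
    torder = {g: i for i, g in enumerate(GRANDPARENT_TYPES)}

    def key(name: str):
        m = re.match(r"beta\[(.+)~(.+)\]", name)
        if m:
            focal, pred = m.groups()
            f = torder.get(focal, 99)
            if pred.endswith("_alive"):
                return (0, f, torder.get(pred.removesuffix("_alive"), 99), name)
            return (1, f, 0, name)
        if name.startswith("alpha["):
            return (2, torder.get(name[6:-1], 99), 0, name)
        if name.startswith("lambda["):
            return (3, 0, 0, name)
        if name.startswith("tau["):
            return (4, 0, 0, name)
        if name.startswith("psi["):
            return (5, 0, 0, name)
        if name.startswith("rho["):
            return (6, 0, 0, name)
        return (7, 0, 0, name)

    return sorted(names, key=key)


def summarize(pdraws: PosteriorDraws, mass: float = 0.95,
              derive_correlations: bool = True) -> pd.DataFrame:
    """Summary table: median, HPD, one-tailed p, PSRF, effective draws.

    One row per named parameter, ordered to mirror the study's reporting
    (structural blocks, then measurement and covariance parameters), with
    latent correlations derived per draw from the Psi draws appended.
    """
    if pdraws.draws.size == 0:
        raise ValueError("no draws to summarize")
    series: dict[str, np.ndarray] = {n: pdraws.get(n) for n in pdraws.names}
    if derive_correlations:
        series.update(_correlation_draws(pdraws))
    rows = []
    for name in _report_order(list(series)):
        ch = series[name]                      # (n_chains, n_kept)
        pooled = ch.reshape(-1)
        lo, hi = hpd_interval(pooled, mass)
        if ch.shape[0] >= 2:
            r = psrf(list(ch))
        else:
            r = float("nan")
        degenerate = not np.isfinite(r)
        try:
            ess = effective_sample_size(ch)
        except Exception:
            ess = float("nan")
        rows.append({
            "parameter": name,
            "median": float(np.median(pooled)),
            "hpd_lo": lo,
            "hpd_hi": hi,
            "p_one_tailed": one_tailed_p(pooled),
            "psrf": r,
            "ess": ess,
            "psrf_degenerate": degenerate,
            "converged_strict": bool(r < PSRF_STRICT) if np.isfinite(r) else False,
            "converged_lenient": bool(r < PSRF_LENIENT) if np.isfinite(r) else False,
        })
    return pd.DataFrame(rows).set_index("parameter")


def structural_block(summary: pd.DataFrame) -> pd.DataFrame:
    """Structural report rows: alive-flag coefficients by focal block."""
    idx = [n for n in summary.index
           if re.match(r"beta\[.+~.+_alive\]", n)]
    return summary.loc[idx, ["median", "hpd_lo", "hpd_hi", "p_one_tailed", "psrf"]]


def correlation_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Posterior-median latent correlation matrix."""
    mat = pd.DataFrame(np.eye(len(GRANDPARENT_TYPES)),
                       index=GRANDPARENT_TYPES, columns=GRANDPARENT_TYPES)
    pat = re.compile(r"rho\[(.+),(.+)\]")
    for n in summary.index:
        m = pat.match(n)
        if m:
            a, b = m.groups()
            if a in mat.index and b in mat.columns:
                mat.loc[a, b] = mat.loc[b, a] = summary.loc[n, "median"]
    return mat
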