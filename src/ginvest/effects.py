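"""Probit marginal effects and phantom-variable sensitivity analysis.

Marginal effects express a fitted structural coefficient as the change in the
probability of each observed category of the marker item when a predictor of
interest flips 0 -> 1 with all other covariates at their sample means.  By
default probabilities are population-averaged over the focal factor's
residual (total underlying SD sqrt(lambda^2 * zeta + 1)); a conditional
(zeta = 0) mode is available.

The sensitivity analysis mimics an unmeasured within-lineage confounder
(e.g. household resources) with a phantom variable: an indicator-less latent
with fixed mean 0 / variance 1 and equal fixed paths gamma into the spouse's
survival flag and the focal investment factor, at 1x and 2x a chosen
confounding strength (default: the largest within-lineage effect in the base
fit, re-computed from the current fit).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import PosteriorDraws, build_engine
from .preprocess import DesignData
from .spec import (
    GRANDPARENT_TYPES,
    LINEAGE,
    ChainConfig,
    ModelSpec,
    PhantomSpec,
)
from .summary import summarize

#: within-lineage ordered (exposure, outcome) spousal pairs
WITHIN_LINEAGE_PAIRS = (
    ("MGF", "MGM"), ("MGM", "MGF"), ("PGF", "PGM"), ("PGM", "PGF"),
)


@dataclass
class Scenario:
    """One marginal-effect contrast: a focal factor, the predictor to flip,
    the marker item whose category probabilities are reported."""

    focal: str
    predictor: str                 # e.g. "MGF_alive"
    marker_item: str = "Q38"


def category_probabilities(thresholds, linear_predictor: float,
                           latent_sd_total: float) -> np.ndarray:
    """Ordinal category probabilities under the probit link.

    P(c) = Phi((tau_c - lp)/s) - Phi((tau_{c-1} - lp)/s), with tau_0 = -inf
    and tau_K = +inf; s is the total underlying SD (1 for conditional
    probabilities, sqrt(lambda^2 zeta + 1) for population-averaged ones).
    """
    from scipy.special import ndtr

    tau = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if latent_sd_total <= 0:
        raise ValueError("latent_sd_total must be > 0")
    z = (tau - linear_predictor) / latent_sd_total
    cdf = np.concatenate([[0.0], ndtr(z), [1.0]])
    return np.diff(cdf)


def _median(summary: pd.DataFrame, name: str) -> float:
    return float(summary.loc[name, "median"])


def marginal_effect_table(summary: pd.DataFrame, spec: ModelSpec,
                          design: DesignData, scenarios=None,
                          averaged: bool = True,
                          draws: PosteriorDraws | None = None) -> pd.DataFrame:
    """Category probabilities of the marker item with each scenario's
    predictor at 0 and at 1, other covariates at sample means.

    Evaluated at posterior medians by default; passing ``draws`` propagates
    the full posterior instead (per-draw probabilities, summarised by their
    median).  Returns one row per (scenario, predictor value) with
    probability columns ``P(cat k)``.
    """
    from scipy.special import ndtr

    gi = {g: i for i, g in enumerate(GRANDPARENT_TYPES)}
    marker = spec.marker_item
    ncat = next(it.n_categories for it in spec.items if it.name == marker)

    if draws is not None:
        def get(name: str) -> np.ndarray:
            return draws.pooled(name)
    else:
        def get(name: str) -> np.ndarray:
            return np.array([_median(summary, name)])

    tau = np.stack([get(f"tau[{marker},{k + 1}]") for k in range(ncat - 1)],
                   axis=1)                                  # (D, K-1)
    if np.any(np.diff(tau, axis=1) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if scenarios is None:
        scenarios = default_scenarios()
    rows = []
    for sc in scenarios:
        preds = spec.structural.predictors[sc.focal]
        if sc.predictor not in preds:
            raise ValueError(
                f"scenario predictor {sc.predictor!r} not in {sc.focal}'s design")
        zeta = get(f"psi[{sc.focal},{sc.focal}]")
        s = np.sqrt(1.0 * zeta + 1.0) if averaged else np.ones_like(zeta)
        alpha_name = f"alpha[{sc.focal}]"
        has_alpha = alpha_name in (draws.names if draws is not None else summary.index)
        lp0 = get(alpha_name) if has_alpha else np.zeros_like(zeta)
        for pred in preds:
            if pred == sc.predictor:
                continue
            b = get(f"beta[{sc.focal}~{pred}]")
            xbar = 0.0 if pred == "age" else float(
                design.alive[:, gi[pred.removesuffix("_alive")]].mean())
            lp0 = lp0 + b * xbar
        b_int = get(f"beta[{sc.focal}~{sc.predictor}]")
        for v in (0, 1):
            lp = lp0 + b_int * v                            # (D,)
            z = (tau - lp[:, None]) / s[:, None]
            cdf = np.concatenate([np.zeros((z.shape[0], 1)), ndtr(z),
                                  np.ones((z.shape[0], 1))], axis=1)
            probs = np.median(np.diff(cdf, axis=1), axis=0)
            row = {"focal": sc.focal, "predictor": sc.predictor, "value": v}
            row.update({f"P(cat {k + 1})": float(p) for k, p in enumerate(probs)})
            rows.append(row)
    return pd.DataFrame(rows)


def default_scenarios() -> list[Scenario]:
    """The contrasts highlighted in the study: the within-lineage maternal
    effect and the cross-lineage effects of a living maternal grandmother."""
    return [
        Scenario(focal="MGM", predictor="MGF_alive"),
        Scenario(focal="PGM", predictor="MGM_alive"),
        Scenario(focal="PGF", predictor="MGM_alive"),
    ]


# ----------------------------------------------------------------------
# phantom sensitivity
# ----------------------------------------------------------------------
def add_phantom(spec: ModelSpec, phantom: PhantomSpec, multiplier: float = 1.0) -> ModelSpec:
    """Return a copy of ``spec`` with one phantom confounder added: a fixed
    N(0,1) latent with paths multiplier*gamma into the focal latent and into
    the spouse-survival flag (switched to endogenous via a linear auxiliary
    equation).  Between-lineage targets are rejected."""
    if LINEAGE[phantom.exposure_type] != LINEAGE[phantom.outcome_type]:
        raise ValueError("phantom confounding is modelled within-lineage only")
    new = ModelSpec.from_dict(spec.to_dict())
    new.phantoms.append(PhantomSpec(
        exposure_type=phantom.exposure_type,
        outcome_type=phantom.outcome_type,
        gamma=phantom.gamma * multiplier,
        auxiliary=phantom.auxiliary,
    ))
    return new


@dataclass
class PhantomScan:
    """Configuration of a sensitivity scan."""

    pairs: tuple = WITHIN_LINEAGE_PAIRS
    gamma: float | None = None          # None: largest within-lineage base effect
    multipliers: tuple = (1.0, 2.0)
    auxiliary: str = "linear"


@dataclass
class SensitivityResult:
    """Side-by-side coefficient summaries of base and confounded fits."""

    table: pd.DataFrame
    gamma: float
    summaries: dict = field(default_factory=dict)   # multiplier -> summary frame
    draws: dict = field(default_factory=dict)       # multiplier -> PosteriorDraws


def _alive_coef_names(spec: ModelSpec) -> list[str]:
    names = []
    for g in GRANDPARENT_TYPES:
        for pred in spec.structural.predictors.get(g, []):
            if pred.endswith("_alive"):
                names.append(f"beta[{g}~{pred}]")
    return names


def within_lineage_coef_names() -> list[str]:
    return [f"beta[{out}~{exp}_alive]" for exp, out in WITHIN_LINEAGE_PAIRS]


def sensitivity_scan(spec: ModelSpec, design: DesignData, chain_config: ChainConfig,
                     scan: PhantomScan | None = None,
                     base_draws: PosteriorDraws | None = None,
                     mass: float = 0.95) -> SensitivityResult:
    """Fit the base model and phantom-confounded variants; tabulate the
    structural coefficients side by side.

    Coefficients whose HPD excludes 0 in the base fit but not under some
    confounding multiplier are flagged ``sign_unstable``.
    """
    scan = scan or PhantomScan()
    if base_draws is None:
        base_draws = build_engine(spec, design).run_chains(chain_config)
    base_summary = summarize(base_draws)
    coef_names = _alive_coef_names(spec)

    gamma = scan.gamma
    if gamma is None:
        gamma = max(abs(float(base_summary.loc[n, "median"]))
                    for n in within_lineage_coef_names() if n in base_summary.index)

    summaries = {0.0: base_summary}
    all_draws = {0.0: base_draws}
    for mult in scan.multipliers:
        sp = ModelSpec.from_dict(spec.to_dict())
        for exp, out in scan.pairs:
            sp = add_phantom(sp, PhantomSpec(exposure_type=exp, outcome_type=out,
                                             gamma=gamma, auxiliary=scan.auxiliary),
                             multiplier=mult)
        drw = build_engine(sp, design).run_chains(chain_config)
        all_draws[mult] = drw
        summaries[mult] = summarize(drw)

    rows = []
    for name in coef_names:
        m = re.match(r"beta\[(.+)~(.+)_alive\]", name)
        row = {"focal": m.group(1), "predictor": m.group(2) + "_alive"}
        base_excl = None
        unstable = False
        for mult, summ in summaries.items():
            tag = "base" if mult == 0.0 else f"x{mult:g}"
            med = float(summ.loc[name, "median"])
            lo, hi = float(summ.loc[name, "hpd_lo"]), float(summ.loc[name, "hpd_hi"])
            row[f"{tag}_median"] = med
            row[f"{tag}_hpd_lo"] = lo
            row[f"{tag}_hpd_hi"] = hi
            excl = lo > 0 or hi < 0
            if mult == 0.0:
                base_excl = excl
            elif base_excl and not excl:
                unstable = True
        row["sign_unstable"] = unstable
        rows.append(row)
    table = pd.DataFrame(rows)
    return SensitivityResult(table=table, gamma=float(gamma),
                             summaries=summaries, draws=all_draws)
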