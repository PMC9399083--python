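"""Model/Results interface to the grandparental-investment BSEM.

`InvestmentModel` is built from a grandchild-level survey table (applying the
study's exclusion and recoding rules on construction); `fit()` runs the Gibbs
sampler and returns an `InvestmentResults` carrying posterior draws, point and
interval estimates, convergence diagnostics, marginal effects and the phantom
sensitivity analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import effects as _effects
from .engine import PosteriorDraws, build_engine
from .preprocess import DesignData, apply_exclusions, encode_design, ExclusionLog
from .spec import ChainConfig, ModelSpec, build_default_spec, validate_spec
from .summary import (
    PSRF_STRICT,
    correlation_matrix,
    structural_block,
    summarize,
)


class InvestmentModel:
    """Bayesian SEM of grandparental investment on grandparent survival.

    Parameters
    ----------
    table : pandas.DataFrame
        Grandchild rows with ``age``, four ``<TYPE>_alive`` flags and the
        sixteen ordinal response columns (``Q15_MGM`` ... ``Q38_PGF``);
        an optional ``co_resident`` flag feeds the exclusion rules.
    spec : ModelSpec, optional
        Defaults to the study's model (marker Q38, free Q15 loading, shared
        thresholds, full latent covariance).
    apply_rules : bool
        Apply the exclusion rules on construction (default True).
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec | None = None,
                 apply_rules: bool = True):
        self.spec = spec or build_default_spec()
        report = validate_spec(self.spec)
        if not report.ok:
            raise ValueError("invalid model spec: " + "; ".join(report.violations))
        if apply_rules:
            self.table, self.exclusion_log = apply_exclusions(table, self.spec)
        else:
            self.table, self.exclusion_log = table.reset_index(drop=True), ExclusionLog()
        self.design: DesignData = encode_design(self.table, self.spec)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | None = None, schema: dict | None = None,
                 dead_response: str = "error") -> "InvestmentModel":
        from .pipeline import read_survey_csv

        table = read_survey_csv(path, schema=schema, spec=spec,
                                dead_response=dead_response)
        return cls(table, spec=spec)

    @property
    def nobs(self) -> int:
        return self.design.n

    def fit(self, chain_config: ChainConfig | None = None, *, chains: int = 3,
            iterations: int = 300_000, burnin: int = 150_000, thin: int = 50,
            seed: int = 0, progress=None) -> "InvestmentResults":
        """Run the Gibbs sampler; defaults mirror the study's MCMC settings."""
        cfg = chain_config or ChainConfig(n_chains=chains, iterations=iterations,
                                          burnin=burnin, thin=thin, seed=seed)
        engine = build_engine(self.spec, self.design)
        draws = engine.run_chains(cfg, progress=progress)
        return InvestmentResults(self, draws)


class InvestmentResults:
    """Posterior estimates, intervals, diagnostics and derived effects."""

    def __init__(self, model: InvestmentModel, draws: PosteriorDraws):
        self.model = model
        self.draws = draws
        self._summary: pd.DataFrame | None = None

    # -- summaries -----------------------------------------------------
    @property
    def summary_frame(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = summarize(self.draws)
        return self._summary

    @property
    def params(self) -> pd.Series:
        return self.summary_frame["median"]

    @property
    def hpd(self) -> pd.DataFrame:
        return self.summary_frame[["hpd_lo", "hpd_hi"]]

    @property
    def psrf(self) -> pd.Series:
        return self.summary_frame["psrf"]

    @property
    def converged(self) -> bool:
        """All finite PSRFs below the strict 1.1 threshold."""
        r = self.psrf.to_numpy()
        return bool(np.all(r[np.isfinite(r)] < PSRF_STRICT))

    def structural_table(self) -> pd.DataFrame:
        """Alive-flag coefficient block (table 1 of the output bundle)."""
        return structural_block(self.summary_frame)

    def correlation_table(self) -> pd.DataFrame:
        """Posterior-median latent correlation matrix (table 2 of the output bundle)."""
        return correlation_matrix(self.summary_frame)

    def summary(self, digits: int = 3) -> str:
        """Formatted report: structural block plus latent correlations."""
        fmt = f"{{:.{digits}f}}".format
        lines = ["Grandparental investment BSEM — structural coefficients",
                 "(posterior median, 95% HPD, one-tailed p, PSRF)", ""]
        st = self.structural_table()
        lines.append(st.to_string(float_format=fmt))
        lines.append("")
        lines.append("Latent investment correlations (posterior medians):")
        lines.append(self.correlation_table().to_string(float_format=fmt))
        n_bad = int((self.psrf[np.isfinite(self.psrf)] >= PSRF_STRICT).sum())
        lines.append("")
        lines.append(f"n = {self.model.nobs}; chains = {self.draws.n_chains}; "
                     f"retained draws/chain = {self.draws.draws.shape[1]}; "
                     f"parameters with PSRF >= {PSRF_STRICT}: {n_bad}")
        return "\n".join(lines)

    # -- derived analyses ---------------------------------------------
    def marginal_effects(self, scenarios=None, averaged: bool = True,
                         propagate: bool = False) -> pd.DataFrame:
        """Marker-item category probabilities with each scenario's predictor
        at 0 and 1, other covariates at sample means.  ``propagate=True``
        pushes every posterior draw through the probability transform instead
        of evaluating at the medians."""
        return _effects.marginal_effect_table(
            self.summary_frame, self.model.spec, self.model.design,
            scenarios=scenarios, averaged=averaged,
            draws=self.draws if propagate else None)

    def sensitivity(self, scan: "_effects.PhantomScan | None" = None,
                    chain_config: ChainConfig | None = None) -> "_effects.SensitivityResult":
        """Phantom-confounder sensitivity scan, reusing this fit as the base."""
        cfg = chain_config or self.draws.config
        return _effects.sensitivity_scan(self.model.spec, self.model.design, cfg,
                                         scan=scan, base_draws=self.draws)

    # -- persistence ----------------------------------------------------
    def save_draws(self, path) -> None:
        """Rectangular draws file (one row per retained iteration)."""
        self.draws.to_csv(path)
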