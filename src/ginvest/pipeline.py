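"""End-to-end workflows: config, survey CSV I/O, result bundles.

The pipeline is a pure function of (input file, config, seed): all outputs
are reproducible byte-for-byte; wall-clock information goes only to the
stderr log.  Every result file carries the config hash and seed in a
``#``-comment header line; machine-readable metadata sits in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GeneratorTruth, generate_cohort
from .effects import PhantomScan
from .model import InvestmentModel, InvestmentResults
from .preprocess import DataError, SchemaError
from .spec import (
    GRANDPARENT_TYPES,
    ITEM_CATEGORIES,
    ChainConfig,
    ModelSpec,
    build_default_spec,
)

log = logging.getLogger("ginvest")

_MODES = ("simulate", "fit", "sensitivity", "recover")


@dataclass
class RunConfig:
    """Declarative run description (CLI flags map onto these fields)."""

    mode: str = "fit"
    input: str | None = None            # survey CSV (fit/sensitivity)
    outdir: str = "ginvest_out"
    seed: int = 0
    n: int = 1411                       # cohort size (simulate/recover)
    chains: int = 3
    iterations: int = 300_000
    burnin: int = 150_000
    thin: int = 50
    quick: bool = False                 # reduced preset for smoke runs
    plots: bool = True
    dead_response: str = "error"        # or "mask"
    spec_overrides: dict = field(default_factory=dict)
    truth_overrides: dict = field(default_factory=dict)
    scan_gamma: float | None = None
    scan_multipliers: tuple = (1.0, 2.0)
    schema: dict | None = None          # role -> column-name map for the CSV

    def chain_config(self) -> ChainConfig:
        if self.quick:
            return ChainConfig(n_chains=min(self.chains, 2), iterations=2000,
                               burnin=1000, thin=2, seed=self.seed)
        return ChainConfig(n_chains=self.chains, iterations=self.iterations,
                           burnin=self.burnin, thin=self.thin, seed=self.seed)

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {_MODES}")
        if self.mode in ("fit", "sensitivity") and not self.input:
            raise ValueError(f"mode {self.mode!r} requires an input CSV path")
        self.chain_config().validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scan_multipliers"] = list(self.scan_multipliers)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if "scan_multipliers" in d:
            d["scan_multipliers"] = tuple(d["scan_multipliers"])
        return RunConfig(**d)

    @staticmethod
    def from_yaml_file(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        """Digest of the analysis-relevant configuration (where the outputs
        land does not change what they contain)."""
        d = self.to_dict()
        d.pop("outdir", None)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class ResultBundle:
    """In-memory results plus the files written for one run."""

    config: RunConfig
    outdir: Path
    files: dict = field(default_factory=dict)      # logical name -> path
    tables: dict = field(default_factory=dict)     # logical name -> DataFrame
    metadata: dict = field(default_factory=dict)
    results: InvestmentResults | None = None
    converged: bool = True


# ----------------------------------------------------------------------
# survey CSV contract
# ----------------------------------------------------------------------
def _canonical_columns(spec: ModelSpec) -> list[str]:
    return (["child_id", "age"] + [f"{g}_alive" for g in GRANDPARENT_TYPES]
            + spec.column_names())


def read_survey_csv(path, schema: dict | None = None, spec: ModelSpec | None = None,
                    dead_response: str = "error") -> pd.DataFrame:
    """Read a survey table; empty cells are missing responses.

    ``schema`` maps canonical roles (``child_id``, ``age``, ``MGM_alive``,
    ``Q15_MGM``, ...) to the file's column names.  Category values are
    validated against each item's range; duplicated child ids are rejected;
    a non-empty response for a deceased grandparent is an error by default
    (``dead_response="mask"`` downgrades it to a warning and masks the cell).
    """
    spec = spec or build_default_spec()
    raw = pd.read_csv(path, comment="#")
    schema = schema or {}
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    t = raw.rename(columns=rename)
    required = _canonical_columns(spec)
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if t["child_id"].duplicated().any():
        dup = t.loc[t["child_id"].duplicated(), "child_id"].iloc[0]
        raise DataError(f"duplicated child id {dup!r}")
    ncat = {f"{item}_{g}": K for item, K in ITEM_CATEGORIES.items()
            for g in GRANDPARENT_TYPES}
    for col, K in ncat.items():
        vals = pd.to_numeric(t[col], errors="coerce")
        text_nonempty = t[col].notna() if t[col].dtype == object else t[col].notna()
        bad_parse = text_nonempty & vals.isna()
        if t[col].dtype == object:
            bad_parse &= t[col].astype(str).str.strip() != ""
        if bad_parse.any():
            i = int(np.flatnonzero(bad_parse)[0])
            raise DataError(f"column {col!r}, row {i}: unparseable category "
                            f"{t[col].iloc[i]!r}")
        present = vals.notna()
        out = (vals < 1) | (vals > K) | (vals != vals.round())
        if (present & out).any():
            i = int(np.flatnonzero(present & out)[0])
            raise DataError(f"column {col!r}, row {i}: value {vals.iloc[i]} "
                            f"outside 1..{K}")
        gtype = col.rsplit("_", 1)[1]
        dead = t[f"{gtype}_alive"].astype(float) == 0
        offending = present & dead
        if offending.any():
            i = int(np.flatnonzero(offending)[0])
            msg = (f"column {col!r}, row {i}: response recorded for a deceased "
                   f"grandparent ({gtype})")
            if dead_response == "mask":
                log.warning("%s — masking", msg)
                vals[offending] = np.nan
            else:
                raise DataError(msg)
        t[col] = pd.array(vals, dtype="Int64")
    return t


# ----------------------------------------------------------------------
# output helpers
# ----------------------------------------------------------------------
def _write_table(df: pd.DataFrame, path: Path, header: str,
                 index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index, float_format="%.12g")


def _write_text_table(df: pd.DataFrame, path: Path, header: str,
                      digits: int = 3) -> None:
    """Whitespace-separated formatted table at fixed precision (3 decimals,
    like the study's tables); parses back with str.split()."""
    with open(path, "w") as fh:
        fh.write(header)
        cols = list(df.columns)
        fh.write("parameter " + " ".join(str(c) for c in cols) + "\n")
        for idx, row in df.iterrows():
            cells = []
            for c in cols:
                v = row[c]
                cells.append(f"{v:.{digits}f}" if isinstance(v, (int, float, np.floating))
                             else str(v))
            fh.write(f"{idx} " + " ".join(cells) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_summary(bundle: ResultBundle) -> None:
    """Write manifest (file checksums) and metadata sidecar."""
    outdir = bundle.outdir
    meta_path = outdir / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True, default=str)
    bundle.files["metadata"] = meta_path
    manifest = {name: {"path": p.name, "sha256": _sha256(Path(p))}
                for name, p in sorted(bundle.files.items())}
    if "table3" not in bundle.files:
        manifest["table3"] = {"path": None, "sha256": None, "note": "absent"}
    man_path = outdir / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle.files["manifest"] = man_path


def _diagnostic_plots(res: InvestmentResults, outdir: Path, header_names: int = 4):
    """Trace and autocorrelation panels for the worst-PSRF structural
    coefficients."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = res.summary_frame
    cand = [n for n in summ.index if n.startswith("beta[") and n.endswith("_alive]")]
    worst = sorted(cand, key=lambda n: -(summ.loc[n, "psrf"] if np.isfinite(summ.loc[n, "psrf"]) else 0))
    names = worst[:header_names]
    fig, axes = plt.subplots(len(names), 2, figsize=(9, 2.2 * len(names)),
                             squeeze=False)
    for r, name in enumerate(names):
        ch = res.draws.get(name)
        for c in range(ch.shape[0]):
            axes[r, 0].plot(ch[c], lw=0.4)
        axes[r, 0].set_title(f"trace {name}", fontsize=8)
        pooled = ch.reshape(-1) - ch.mean()
        ac = np.correlate(pooled, pooled, "full")[pooled.size - 1:]
        ac = ac[:50] / ac[0] if ac[0] > 0 else np.zeros(50)
        axes[r, 1].bar(np.arange(ac.size), ac, width=0.8)
        axes[r, 1].set_title(f"autocorrelation {name}", fontsize=8)
    fig.tight_layout()
    path = outdir / "diagnostics.png"
    fig.savefig(path, dpi=100, metadata={"Software": "ginvest"})
    plt.close(fig)
    return path


# ----------------------------------------------------------------------
# the workflows
# ----------------------------------------------------------------------
def run_full_analysis(config: RunConfig) -> ResultBundle:
    """Execute one packaged workflow (simulate / fit / sensitivity / recover).

    Stages: preprocess -> fit -> summaries -> marginal effects
    (-> sensitivity when requested); every output carries the config hash and
    seed; logging goes to stderr; ``bundle.converged`` reflects the PSRF
    flags.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    header = f"# config={chash} seed={config.seed}\n"
    bundle = ResultBundle(config=config, outdir=outdir)
    cfg_echo = config.to_dict()
    cfg_echo.pop("outdir", None)          # placement is not part of the results
    meta: dict = {"config": cfg_echo, "config_hash": chash,
                  "seed": config.seed, "mode": config.mode}

    truth = GeneratorTruth.from_dict({**GeneratorTruth().to_dict(),
                                      **config.truth_overrides})
    n_sim = 300 if (config.quick and config.n == 1411) else config.n

    if config.mode == "simulate":
        log.info("simulating cohort of %d grandchildren (seed %d)", n_sim, config.seed)
        cohort = generate_cohort(truth, n_sim, seed=config.seed)
        csv_path = outdir / "cohort.csv"
        truth_path = outdir / "truth.yaml"
        with open(csv_path, "w") as fh:
            fh.write(header)
            cohort.table.to_csv(fh, index=False)
        with open(truth_path, "w") as fh:
            fh.write(header.replace("# ", "# ", 1))
            fh.write(cohort.truth.to_yaml())
        bundle.files["cohort"] = csv_path
        bundle.files["truth"] = truth_path
        meta["n"] = n_sim
        bundle.metadata = meta
        write_summary(bundle)
        return bundle

    # ---- obtain data -------------------------------------------------
    spec = build_default_spec()
    if config.spec_overrides:
        spec = ModelSpec.from_dict({**spec.to_dict(), **config.spec_overrides})
    if config.mode == "recover":
        log.info("recovery run: simulating %d rows then fitting", n_sim)
        cohort = generate_cohort(truth, n_sim, seed=config.seed)
        table = cohort.table
    else:
        log.info("reading survey table from %s", config.input)
        table = read_survey_csv(config.input, schema=config.schema, spec=spec,
                                dead_response=config.dead_response)
        cohort = None

    model = InvestmentModel(table, spec=spec)
    meta["n_after_exclusions"] = model.nobs
    meta["exclusions"] = model.exclusion_log.as_tuple()
    cfg = config.chain_config()
    log.info("fitting: %d chains x %d iterations (burn-in %d, thin %d)",
             cfg.n_chains, cfg.iterations, cfg.burnin, cfg.thin)
    res = model.fit(chain_config=cfg, progress=_log_progress)
    bundle.results = res
    summ = res.summary_frame

    t1 = res.structural_table()
    _write_table(t1, outdir / "table1_structural.csv", header)
    _write_text_table(t1, outdir / "table1_structural.txt", header)
    bundle.tables["table1"] = t1
    bundle.files["table1"] = outdir / "table1_structural.csv"
    bundle.files["table1_txt"] = outdir / "table1_structural.txt"

    t2 = res.correlation_table()
    _write_table(t2, outdir / "table2_correlations.csv", header)
    bundle.tables["table2"] = t2
    bundle.files["table2"] = outdir / "table2_correlations.csv"

    me = res.marginal_effects()
    _write_table(me, outdir / "marginal_effects.csv", header, index=False)
    bundle.tables["marginal_effects"] = me
    bundle.files["marginal_effects"] = outdir / "marginal_effects.csv"

    diag = summ[["median", "psrf", "ess", "converged_strict", "converged_lenient"]]
    _write_table(diag, outdir / "diagnostics_psrf.csv", header)
    bundle.files["diagnostics"] = outdir / "diagnostics_psrf.csv"

    full = summ.drop(columns=["psrf_degenerate"])
    _write_table(full, outdir / "summary_full.csv", header)
    bundle.files["summary_full"] = outdir / "summary_full.csv"

    draws_path = outdir / "draws.csv"
    with open(draws_path, "w") as fh:
        fh.write(header)
        res.draws.to_dataframe().to_csv(fh, index=False, float_format="%.12g")
    bundle.files["draws"] = draws_path

    with open(outdir / "summary.txt", "w") as fh:
        fh.write(header)
        fh.write(res.summary() + "\n")
    bundle.files["summary_txt"] = outdir / "summary.txt"

    if config.plots:
        bundle.files["plots"] = _diagnostic_plots(res, outdir)

    if config.mode == "sensitivity":
        log.info("sensitivity scan (multipliers %s)", list(config.scan_multipliers))
        scan = PhantomScan(gamma=config.scan_gamma,
                           multipliers=tuple(config.scan_multipliers))
        sens = res.sensitivity(scan=scan, chain_config=cfg)
        t3 = sens.table
        _write_table(t3, outdir / "table3_sensitivity.csv", header, index=False)
        bundle.tables["table3"] = t3
        bundle.files["table3"] = outdir / "table3_sensitivity.csv"
        meta["sensitivity_gamma"] = sens.gamma

    if config.mode == "recover" and cohort is not None:
        rec = recovery_report(res, cohort.truth)
        _write_table(rec, outdir / "recovery.csv", header, index=False)
        bundle.tables["recovery"] = rec
        bundle.files["recovery"] = outdir / "recovery.csv"
        with open(outdir / "truth.yaml", "w") as fh:
            fh.write(header)
            fh.write(cohort.truth.to_yaml())
        bundle.files["truth"] = outdir / "truth.yaml"
        meta["coverage"] = {
            "n_covered": int(rec["covered"].sum()),
            "n_coefficients": int(len(rec)),
        }

    bundle.converged = res.converged
    r = summ["psrf"].to_numpy()
    meta["psrf_max"] = float(np.nanmax(r[np.isfinite(r)])) if np.isfinite(r).any() else None
    meta["converged_strict"] = bool(res.converged)
    bundle.metadata = meta
    write_summary(bundle)
    log.info("done; outputs in %s (converged=%s)", outdir, res.converged)
    return bundle


def recovery_report(res: InvestmentResults, truth: GeneratorTruth) -> pd.DataFrame:
    """Compare fitted structural medians/HPDs with the generating truth."""
    summ = res.summary_frame
    rows = []
    for g in GRANDPARENT_TYPES:
        for pred, bt in truth.beta[g].items():
            name = f"beta[{g}~{pred}]"
            if name not in summ.index:
                continue
            lo, hi = float(summ.loc[name, "hpd_lo"]), float(summ.loc[name, "hpd_hi"])
            med = float(summ.loc[name, "median"])
            rows.append({
                "parameter": name, "truth": bt, "median": med,
                "hpd_lo": lo, "hpd_hi": hi,
                "covered": bool(lo <= bt <= hi),
                "sign_recovered": bool((lo > 0 and bt > 0) or (hi < 0 and bt < 0)),
                "alive_flag": pred.endswith("_alive"),
            })
    return pd.DataFrame(rows)


def _log_progress(chain_id: int, done: int, total: int) -> None:
    log.info("chain %d: %d/%d iterations", chain_id, done, total)


def setup_logging(verbosity: int = 1) -> None:
    level = logging.WARNING if verbosity <= 0 else (
        logging.INFO if verbosity == 1 else logging.DEBUG)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
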