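"""Recoding, exclusion rules and sampler-ready design assembly.

Mirrors the study's data handling: the reverse-coded item is re-oriented,
grandchildren with no living grandparent are dropped, then co-residing
grandchildren, then rows with no responses at all or missing age; the
remaining rows are encoded as 0-based category codes with an explicit
missingness mask (never a sentinel category) plus per-factor regression
designs (the other three alive flags and centered age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spec import GRANDPARENT_TYPES, ModelSpec


class SchemaError(ValueError):
    """A required column is absent or malformed."""


class DataError(ValueError):
    """A cell value violates its declared range or missingness contract."""


def reverse_scale(category, n_categories: int):
    """Map category c on a 1..K scale to K + 1 - c; missing stays missing."""
    if category is None or (isinstance(category, float) and np.isnan(category)) or category is pd.NA:
        return category
    c = int(category)
    if not 1 <= c <= n_categories:
        raise DataError(f"category {c} outside 1..{n_categories}")
    return n_categories + 1 - c


@dataclass
class ExclusionLog:
    """Row-drop counts, in rule order."""

    no_living_grandparent: int = 0
    co_residing: int = 0
    empty_or_missing_age: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.no_living_grandparent, self.co_residing, self.empty_or_missing_age)


def apply_exclusions(table: pd.DataFrame, spec: ModelSpec | None = None):
    """Apply the study's exclusion rules in order; returns (table, log).

    Order: (1) no living grandparent; (2) co-residing with grandparents
    (column ``co_resident``, if present); (3) no response in any of the
    items, or missing age.
    """
    spec = spec or _default_spec()
    log = ExclusionLog()
    t = table
    alive_cols = [f"{g}_alive" for g in GRANDPARENT_TYPES]
    for c in alive_cols:
        if c not in t.columns:
            raise SchemaError(f"missing required column {c!r}")
    keep = t[alive_cols].sum(axis=1) > 0
    log.no_living_grandparent = int((~keep).sum())
    t = t[keep]
    if "co_resident" in t.columns:
        keep = t["co_resident"].fillna(0).astype(int) == 0
        log.co_residing = int((~keep).sum())
        t = t[keep]
    resp_cols = [c for c in spec.column_names() if c in t.columns]
    if "age" not in t.columns:
        raise SchemaError("missing required column 'age'")
    no_resp = t[resp_cols].isna().all(axis=1) if resp_cols else pd.Series(True, index=t.index)
    keep = ~(no_resp | t["age"].isna())
    log.empty_or_missing_age = int((~keep).sum())
    t = t[keep]
    return t.reset_index(drop=True), log


def _default_spec() -> ModelSpec:
    from .spec import build_default_spec

    return build_default_spec()


@dataclass
class DesignData:
    """Sampler-ready arrays for the four-factor model."""

    codes: np.ndarray            # (n, J) 0-based categories, -1 missing
    mask: np.ndarray             # (n, J) bool, True where a response exists
    alive: np.ndarray            # (n, 4) 0/1
    age: np.ndarray              # (n,) raw years
    age_center: float            # sample mean used for centering
    X: dict = field(default_factory=dict)        # factor -> (n, p) design
    x_names: dict = field(default_factory=dict)  # factor -> column names
    column_names: list = field(default_factory=list)
    n_categories: list = field(default_factory=list)   # per column

    @property
    def n(self) -> int:
        return self.codes.shape[0]


def encode_design(table: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Encode a post-exclusion table as sampler-ready design data.

    Re-orients reverse-coded items, converts 1-based categories to 0-based
    codes with an explicit mask, validates ranges, and builds each factor's
    design matrix (free intercept except for the reference type, the other
    three alive flags, and age centered at its sample mean).
    """
    n = len(table)
    cols = spec.column_names()
    for c in [f"{g}_alive" for g in GRANDPARENT_TYPES] + ["age"] + cols:
        if c not in table.columns:
            raise SchemaError(f"missing required column {c!r}")

    items_by_name = {it.name: it for it in spec.items}
    codes = np.full((n, len(cols)), -1, dtype=np.int64)
    ncats: list[int] = []
    for j, col in enumerate(cols):
        item_name = col.rsplit("_", 1)[0]
        item = items_by_name[item_name]
        ncats.append(item.n_categories)
        vals = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        present = ~np.isnan(vals)
        v = vals[present]
        if v.size and (np.any(v < 1) or np.any(v > item.n_categories) or np.any(v != np.round(v))):
            bad = np.flatnonzero(present)[
                np.flatnonzero((v < 1) | (v > item.n_categories) | (v != np.round(v)))[0]
            ]
            raise DataError(
                f"column {col!r}, row {bad}: value {vals[bad]} outside 1..{item.n_categories}"
            )
        iv = v.astype(np.int64)
        if item.reverse_coded:
            iv = item.n_categories + 1 - iv
        codes[present, j] = iv - 1
    mask = codes >= 0

    alive = table[[f"{g}_alive" for g in GRANDPARENT_TYPES]].to_numpy(dtype=np.int8)
    age = pd.to_numeric(table["age"], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(age)):
        raise DataError("missing age after exclusions")
    age_center = float(age.mean()) if n else 0.0
    age_c = age - age_center

    X: dict = {}
    x_names: dict = {}
    gi = {g: i for i, g in enumerate(GRANDPARENT_TYPES)}
    for g in GRANDPARENT_TYPES:
        names: list[str] = []
        cols_g: list[np.ndarray] = []
        if spec.structural.has_free_intercept(g):
            names.append("intercept")
            cols_g.append(np.ones(n))
        for pred in spec.structural.predictors.get(g, []):
            names.append(pred)
            if pred == "age":
                cols_g.append(age_c)
            else:
                cols_g.append(alive[:, gi[pred.removesuffix("_alive")]].astype(float))
        X[g] = np.column_stack(cols_g) if cols_g else np.empty((n, 0))
        x_names[g] = names

    return DesignData(
        codes=codes,
        mask=mask,
        alive=alive,
        age=age,
        age_center=age_center,
        X=X,
        x_names=x_names,
        column_names=cols,
        n_categories=ncats,
    )
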