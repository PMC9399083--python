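"""Declarative description of the grandparental-investment BSEM.

The model has one latent "investment" factor per grandparent type (maternal
grandmother MGM, maternal grandfather MGF, paternal grandmother PGM, paternal
grandfather PGF), each measured by four ordinal questionnaire items and
regressed on the alive/dead status of the other three grandparent types plus
grandchild age.  This module holds the declarative spec — factors, items,
invariance constraints, structural design, priors, identification rules — and
its validation and (de)serialisation; the numerics live in :mod:`ginvest.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: The four grandparent types, in canonical (reporting) order.
GRANDPARENT_TYPES: tuple[str, ...] = ("MGM", "MGF", "PGM", "PGF")

#: lineage / sex derived from the type code.
LINEAGE = {"MGM": "maternal", "MGF": "maternal", "PGM": "paternal", "PGF": "paternal"}
SEX = {"MGM": "female", "MGF": "male", "PGM": "female", "PGF": "male"}

#: Questionnaire items and their category counts (Q15/Q26/Q27 are 4-point
#: Likert items, Q38 — financial assistance, the marker — is 3-point).
ITEM_CATEGORIES = {"Q15": 4, "Q26": 4, "Q27": 4, "Q38": 3}
ITEM_ORDER: tuple[str, ...] = ("Q15", "Q26", "Q27", "Q38")
MARKER_ITEM = "Q38"
REVERSE_CODED_ITEMS = ("Q26",)


@dataclass(frozen=True)
class GrandparentType:
    """A grandparent type code with its derived lineage and sex."""

    code: str

    def __post_init__(self) -> None:
        if self.code not in GRANDPARENT_TYPES:
            raise ValueError(f"unknown grandparent type {self.code!r}")

    @property
    def lineage(self) -> str:
        return LINEAGE[self.code]

    @property
    def sex(self) -> str:
        return SEX[self.code]

    def spouse(self) -> "GrandparentType":
        """The other member of the same lineage (the within-lineage pair)."""
        pair = {"MGM": "MGF", "MGF": "MGM", "PGM": "PGF", "PGF": "PGM"}
        return GrandparentType(pair[self.code])


@dataclass
class ItemSpec:
    name: str
    n_categories: int
    reverse_coded: bool = False
    is_marker: bool = False

    @property
    def n_thresholds(self) -> int:
        return self.n_categories - 1


@dataclass
class InvariancePattern:
    """Partial measurement invariance across the four grandparent types.

    Thresholds are shared by all types; every loading is shared except
    ``free_loading_item``, which gets a type-specific loading.  The marker
    item's loading is fixed to 1 in every type and can never be the free item.
    """

    thresholds_invariant: bool = True
    free_loading_item: str = "Q15"


@dataclass
class StructuralSpec:
    """Per-factor regression design: the other three alive flags plus age.

    ``predictors`` maps each focal type to its predictor names
    (``"<TYPE>_alive"`` or ``"age"``).  The reference type's structural
    intercept is fixed to zero to identify latent locations (thresholds being
    shared makes latent means comparable across types).
    """

    predictors: dict[str, list[str]] = field(default_factory=dict)
    reference_type: str = "MGM"

    @staticmethod
    def default() -> "StructuralSpec":
        preds = {
            g: [f"{h}_alive" for h in GRANDPARENT_TYPES if h != g] + ["age"]
            for g in GRANDPARENT_TYPES
        }
        return StructuralSpec(predictors=preds)

    def has_free_intercept(self, gtype: str) -> bool:
        return gtype != self.reference_type


@dataclass
class PriorSet:
    """Prior hyperparameters (variances, not standard deviations)."""

    beta_mean: float = 0.0
    beta_var: float = 100.0**2          # structural coefficients & free intercepts
    loading_mean: float = 0.0
    loading_var: float = 5.0
    threshold_mean: float = 0.0
    threshold_var: float = 1.0
    psi_df: float = 5.0                 # inverse-Wishart df for the 4x4 case
    psi_scale_diag: float = 1.0         # scale matrix = psi_scale_diag * I


@dataclass
class ChainConfig:
    n_chains: int = 3
    iterations: int = 300_000
    burnin: int = 150_000
    thin: int = 50
    seed: int = 0

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burnin) // self.thin

    def validate(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if (self.iterations - self.burnin) % self.thin != 0:
            import warnings

            warnings.warn(
                "(iterations - burnin) is not divisible by thin; the last "
                f"partial stride is dropped ({self.n_retained} draws retained)",
                stacklevel=2)


@dataclass
class PhantomSpec:
    """An indicator-less latent mimicking within-lineage unmeasured confounding.

    The phantom has fixed mean 0 and variance 1, a fixed path ``mult * gamma``
    into the focal latent's structural equation and a fixed path
    ``mult * gamma`` into the spouse-survival flag, which becomes endogenous
    through a linear auxiliary equation.
    """

    exposure_type: str            # grandparent whose alive flag is confounded
    outcome_type: str             # focal factor receiving the confounded path
    gamma: float = 0.0
    auxiliary: str = "linear"     # "linear" (default) or "probit"

    def validate(self) -> None:
        if LINEAGE[self.exposure_type] != LINEAGE[self.outcome_type]:
            raise ValueError(
                "phantom confounding is within-lineage only: "
                f"{self.exposure_type} and {self.outcome_type} differ in lineage"
            )
        if self.exposure_type == self.outcome_type:
            raise ValueError("phantom exposure and outcome must be a spousal pair")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0 (resource-availability confounding)")


@dataclass
class ModelSpec:
    """The full measurement + structural model description."""

    items: list[ItemSpec] = field(default_factory=list)
    invariance: InvariancePattern = field(default_factory=InvariancePattern)
    structural: StructuralSpec = field(default_factory=StructuralSpec.default)
    priors: PriorSet = field(default_factory=PriorSet)
    residual_var: float = 1.0           # indicator residual variance (probit scale)
    phantoms: list[PhantomSpec] = field(default_factory=list)

    # ---- derived counts -------------------------------------------------
    @property
    def marker_item(self) -> str:
        for it in self.items:
            if it.is_marker:
                return it.name
        raise ValueError("spec has no marker item")

    @property
    def n_observed_columns(self) -> int:
        return len(self.items) * len(GRANDPARENT_TYPES)

    def n_free_loadings(self) -> int:
        """Free loading parameters under the invariance pattern.

        The marker is fixed at 1; the free item contributes one loading per
        type; every other item contributes a single shared loading.
        """
        n = 0
        for it in self.items:
            if it.is_marker:
                continue
            n += len(GRANDPARENT_TYPES) if it.name == self.invariance.free_loading_item else 1
        return n

    def n_threshold_params(self) -> int:
        """Total entries across the shared threshold vectors."""
        return sum(it.n_thresholds for it in self.items)

    def column_names(self) -> list[str]:
        """Observed response columns, item-major then type (``Q15_MGM``, ...)."""
        return [f"{it.name}_{g}" for it in self.items for g in GRANDPARENT_TYPES]

    # ---- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        items = [ItemSpec(**x) for x in d.get("items", [])]
        inv = InvariancePattern(**d.get("invariance", {}))
        struct = StructuralSpec(**d.get("structural", {}))
        priors = PriorSet(**d.get("priors", {}))
        phantoms = [PhantomSpec(**x) for x in d.get("phantoms", [])]
        return ModelSpec(
            items=items,
            invariance=inv,
            structural=struct,
            priors=priors,
            residual_var=d.get("residual_var", 1.0),
            phantoms=phantoms,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "ModelSpec":
        return ModelSpec.from_dict(yaml.safe_load(text))


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


def build_default_spec() -> ModelSpec:
    """The default model: 4 factors x 4 ordinal items.

    Q38 is the marker (loading fixed at 1 in all four factors), Q26/Q27
    loadings are shared across types, Q15's loading is type-specific,
    thresholds are shared, the latent error covariance is a full 4x4 matrix,
    and each factor is regressed on the other three alive flags plus
    (centered) grandchild age.
    """
    items = [
        ItemSpec(
            name=name,
            n_categories=ITEM_CATEGORIES[name],
            reverse_coded=name in REVERSE_CODED_ITEMS,
            is_marker=name == MARKER_ITEM,
        )
        for name in ITEM_ORDER
    ]
    return ModelSpec(items=items)


def validate_spec(spec: ModelSpec) -> ValidationReport:
    """Check estimability; problems are reported, never raised."""
    rep = ValidationReport()
    markers = [it.name for it in spec.items if it.is_marker]
    if len(markers) != 1:
        rep.add(f"exactly one marker item required, found {len(markers)}")
    for it in spec.items:
        if not (2 <= it.n_categories <= 7):
            rep.add(f"item {it.name}: category count {it.n_categories} outside 2-7")
    if markers and spec.invariance.free_loading_item in markers:
        rep.add("free (non-invariant) loading item must not be the marker")
    known_items = {it.name for it in spec.items}
    if spec.invariance.free_loading_item not in known_items:
        rep.add(f"free loading item {spec.invariance.free_loading_item!r} unknown")
    # structural design
    for g, preds in spec.structural.predictors.items():
        if f"{g}_alive" in preds:
            rep.add(f"self-regression: factor {g} regressed on {g}_alive")
        for p in preds:
            base = p.removesuffix("_alive")
            if p != "age" and base not in GRANDPARENT_TYPES:
                rep.add(f"factor {g}: unknown predictor {p!r}")
    if spec.structural.reference_type not in GRANDPARENT_TYPES:
        rep.add(f"unknown reference type {spec.structural.reference_type!r}")
    # priors
    pr = spec.priors
    for nm, v in [("beta_var", pr.beta_var), ("loading_var", pr.loading_var),
                  ("threshold_var", pr.threshold_var), ("psi_scale_diag", pr.psi_scale_diag)]:
        if v <= 0:
            rep.add(f"prior variance {nm} must be > 0, got {v}")
    dim = len(GRANDPARENT_TYPES)
    if pr.psi_df <= dim - 1:
        rep.add(f"improper IW: df {pr.psi_df} <= dim - 1 = {dim - 1}")
    if spec.residual_var <= 0:
        rep.add("indicator residual variance must be > 0")
    for ph in spec.phantoms:
        try:
            ph.validate()
        except ValueError as e:
            rep.add(str(e))
    return rep
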