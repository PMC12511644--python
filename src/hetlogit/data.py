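"""Data containers, validation and I/O for choice panels and binary-outcome panels.

Choice data are held long format: one row per alternative within one choice
task, with a boolean availability flag, a boolean chosen flag and numeric
attribute columns.  Revealed-preference data are one row per person with two
binary product-use outcomes and numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a dataset or specification violates its invariants."""


class ConfigurationError(ValueError):
    """Raised when user configuration (columns, families, labels) is inconsistent."""


# distribution tags and the number of estimated parameters each implies
DIST_TAGS = (
    "fixed",
    "normal",
    "uniform",
    "triangular",
    "lognormal",
    "loguniform",
    "asym_triangular",
    "fm2",
    "fm3",
)

_N_PARAMS = {
    "fixed": 1,
    "normal": 2,
    "uniform": 2,
    "triangular": 2,
    "lognormal": 2,
    "loguniform": 2,
    "asym_triangular": 3,  # 2 when the mode offset c is fixed to 0
    "fm2": 3,
    "fm3": 4,
}

LOG_FAMILIES = ("lognormal", "loguniform")


@dataclass(frozen=True)
class ChoiceDataset:
    """Long-format panel of choice tasks.

    Parameters
    ----------
    table
        One row per alternative-in-task with columns ``person_id``,
        ``task_id``, ``alt_id``, ``available`` (bool), ``chosen`` (bool) and
        one numeric column per attribute.
    attributes
        Names of the numeric attribute columns.
    alt_groups
        Optional labels for groups of alternatives (e.g. ``{"branded":
        ("alt1", "alt2")}``), used for alternative-specific constants and
        share aggregation.
    """

    table: pd.DataFrame
    attributes: tuple[str, ...]
    alt_groups: Mapping[str, tuple] = field(default_factory=dict)

    ID_COLUMNS = ("person_id", "task_id", "alt_id", "available", "chosen")

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        missing = [c for c in self.ID_COLUMNS if c not in t.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        for a in self.attributes:
            if a not in t.columns:
                raise ConfigurationError(f"attribute column not in table: {a!r}")
            vals = pd.to_numeric(t[a], errors="coerce")
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValidationError(f"attribute {a!r} has non-finite values")
        if (t["chosen"].astype(bool) & ~t["available"].astype(bool)).any():
            raise ValidationError("a chosen alternative is marked unavailable")
        grouped = t.groupby(["person_id", "task_id"], sort=False)
        n_avail = grouped["available"].sum()
        if (n_avail < 2).any():
            bad = n_avail[n_avail < 2].index[0]
            raise ValidationError(f"task {bad} has fewer than 2 available alternatives")
        n_chosen = grouped.apply(
            lambda g: int((g["chosen"].astype(bool) & g["available"].astype(bool)).sum()),
            include_groups=False,
        )
        if (n_chosen != 1).any():
            bad = n_chosen[n_chosen != 1].index[0]
            raise ValidationError(
                f"task {bad} has {int(n_chosen.loc[bad])} chosen alternatives (need exactly 1)"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def persons(self) -> np.ndarray:
        """Person identifiers in order of first appearance."""
        return pd.unique(self.table["person_id"])

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def n_tasks(self) -> int:
        return self.table.groupby(["person_id", "task_id"], sort=False).ngroups

    # -- transforms ---------------------------------------------------------
    def dummy_code(self, attribute: str, reference_level) -> "ChoiceDataset":
        """Replace a categorical column by 0/1 indicators for non-reference levels.

        The reference level maps to all-zero indicators, matching the usual
        dummy-coding of attribute levels in choice experiments.
        """
        if attribute not in self.table.columns:
            raise ConfigurationError(f"unknown attribute {attribute!r}")
        col = self.table[attribute]
        levels = list(pd.unique(col))
        if reference_level not in levels:
            raise ValidationError(
                f"reference level {reference_level!r} not found in {attribute!r} "
                f"(levels: {levels})"
            )
        t = self.table.copy()
        new_cols = []
        for lev in levels:
            if lev == reference_level:
                continue
            name = f"{attribute}_{lev}"
            t[name] = (col == lev).astype(float)
            new_cols.append(name)
        t = t.drop(columns=[attribute])
        attrs = tuple(a for a in self.attributes if a != attribute) + tuple(new_cols)
        return ChoiceDataset(t, attrs, dict(self.alt_groups))

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        path,
        column_map: Optional[Mapping[str, str]] = None,
        attributes: Optional[Sequence[str]] = None,
        alt_groups: Optional[Mapping[str, tuple]] = None,
    ) -> "ChoiceDataset":
        """Read a long-format choice panel from CSV.

        ``column_map`` maps the standard names (``person_id``, ``task_id``,
        ``alt_id``, ``available``, ``chosen``) to the file's column names.
        ``available`` may be omitted, in which case all rows are available.
        If ``attributes`` is None, every unmapped column is treated as an
        attribute.
        """
        df = pd.read_csv(path)
        column_map = dict(column_map or {})
        rename = {}
        for std in ("person_id", "task_id", "alt_id", "available", "chosen"):
            src = column_map.get(std, std)
            if src in df.columns:
                rename[src] = std
            elif std != "available":
                raise ConfigurationError(f"column {src!r} (for {std!r}) not in file")
        df = df.rename(columns=rename)
        if "available" not in df.columns:
            df["available"] = True
        df["available"] = df["available"].astype(bool)
        df["chosen"] = df["chosen"].astype(bool)
        if attributes is None:
            attributes = [c for c in df.columns if c not in cls.ID_COLUMNS]
        return cls(df, tuple(attributes), dict(alt_groups or {}))

    def to_csv(self, path) -> None:
        cols = list(self.ID_COLUMNS) + list(self.attributes)
        self.table[cols].to_csv(path, index=False)


read_choice_data = ChoiceDataset.from_csv


@dataclass(frozen=True)
class BinaryPanelDataset:
    """One row per person with two binary outcomes and numeric covariates.

    The outcomes (``cig``, ``ecig`` — cigarette and e-cigarette use in the
    motivating application) may share an individual error component inducing
    correlation between them.
    """

    table: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        t = self.table
        for c in ("person_id", "cig", "ecig"):
            if c not in t.columns:
                raise ConfigurationError(f"missing required column {c!r}")
        if t["person_id"].duplicated().any():
            raise ValidationError("one row per person required")
        for z in self.covariates:
            if z not in t.columns:
                raise ConfigurationError(f"covariate column not in table: {z!r}")
            if not np.isfinite(t[z].to_numpy(dtype=float)).all():
                raise ValidationError(f"covariate {z!r} has non-finite values")
        for c in ("cig", "ecig"):
            vals = set(pd.unique(t[c].astype(int)))
            if not vals <= {0, 1}:
                raise ValidationError(f"outcome {c!r} must be binary 0/1")

    @property
    def n_persons(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path, covariates: Sequence[str] = ()) -> "BinaryPanelDataset":
        return cls(pd.read_csv(path), tuple(covariates))

    def to_csv(self, path) -> None:
        cols = ["person_id", "cig", "ecig"] + list(self.covariates)
        self.table[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class CoefficientSpec:
    """One taste coefficient: its mixing family and the columns it multiplies.

    ``attributes`` lists data columns whose (summed) value the coefficient
    multiplies; an alternative-specific constant instead names an
    ``asc_group`` from the dataset's ``alt_groups`` and multiplies its 0/1
    membership indicator.  ``sign`` applies to the log families (lognormal /
    loguniform), whose support lies strictly on one side of zero; the default
    −1 imposes negative preferences (the usual convention for price, risk and
    harm attributes).  ``equation`` tags revealed-preference coefficients with
    the outcome equation they enter ("cig" or "ecig").
    """

    name: str
    dist: str = "fixed"
    attributes: tuple[str, ...] = ()
    sign: int = -1
    asc_group: Optional[str] = None
    equation: Optional[str] = None
    fix_offset: bool = True  # asym_triangular: fix the mode offset c to 0

    def __post_init__(self):
        if self.dist not in DIST_TAGS:
            raise ConfigurationError(
                f"unknown distribution tag {self.dist!r}; allowed: {DIST_TAGS}"
            )
        if self.sign not in (-1, 1):
            raise ConfigurationError("sign must be +1 or -1")
        if not self.attributes and self.asc_group is None and self.equation is None:
            raise ConfigurationError(
                f"coefficient {self.name!r} has no attributes and is not a constant"
            )
        object.__setattr__(self, "attributes", tuple(self.attributes))

    @property
    def n_params(self) -> int:
        if self.dist == "asym_triangular" and self.fix_offset:
            return 2
        return _N_PARAMS[self.dist]


@dataclass(frozen=True)
class ModelSpec:
    """Full model specification: coefficients, utility space, options.

    ``space`` is "preference" (utility linear in attributes) or "wtp"
    (willingness-to-pay space: non-price coefficients are money-metric and the
    whole bracket is scaled by the price coefficient).  ``rp_error_component``
    configures the shared individual error of the two-equation
    revealed-preference logit: ``{"sign": +1}`` adds +ρ_n to both equations,
    ``{"sign": -1}`` adds −ρ_n to the second.
    """

    coefficients: tuple[CoefficientSpec, ...]
    space: str = "preference"
    price_coefficient: Optional[str] = None
    rp_error_component: Optional[Mapping] = None

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(self.coefficients))
        names = [c.name for c in self.coefficients]
        if len(set(names)) != len(names):
            raise ConfigurationError("coefficient names must be unique")
        if self.space not in ("preference", "wtp"):
            raise ConfigurationError("space must be 'preference' or 'wtp'")
        if self.space == "wtp":
            if self.price_coefficient is None:
                raise ConfigurationError("wtp space requires a price_coefficient")
            if self.price_coefficient not in names:
                raise ConfigurationError(
                    f"price_coefficient {self.price_coefficient!r} not among coefficients"
                )
        if self.rp_error_component is not None:
            if self.rp_error_component.get("sign", 1) not in (-1, 1):
                raise ConfigurationError("rp_error_component sign must be +1 or -1")

    def coefficient(self, name: str) -> CoefficientSpec:
        for c in self.coefficients:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_params(self) -> int:
        k = sum(c.n_params for c in self.coefficients)
        if self.rp_error_component is not None:
            k += 1  # σ_ρ
        return k

    def with_all_fixed(self) -> "ModelSpec":
        """Degenerate copy with every coefficient fixed (plain logit)."""
        coefs = tuple(replace(c, dist="fixed") for c in self.coefficients)
        return ModelSpec(coefs, self.space, self.price_coefficient, None)


@dataclass
class SpecReport:
    n_params: int
    resolved: dict
    messages: list


def validate_spec(spec: ModelSpec, data) -> SpecReport:
    """Check a model spec against a dataset; resolve columns, count parameters.

    Raises :class:`ConfigurationError` listing unresolved attribute columns.
    """
    resolved = {}
    missing = []
    if isinstance(data, ChoiceDataset):
        cols = set(data.attributes)
        for c in spec.coefficients:
            if c.asc_group is not None:
                if c.asc_group not in data.alt_groups:
                    missing.append(f"{c.name}: alt group {c.asc_group!r}")
                else:
                    resolved[c.name] = ("asc", c.asc_group)
                continue
            bad = [a for a in c.attributes if a not in cols]
            if bad:
                missing.append(f"{c.name}: columns {bad}")
            else:
                resolved[c.name] = ("attributes", c.attributes)
        if spec.rp_error_component is not None:
            missing.append("rp_error_component is only valid for BinaryPanelDataset")
    elif isinstance(data, BinaryPanelDataset):
        cols = set(data.covariates)
        for c in spec.coefficients:
            if c.equation not in ("cig", "ecig"):
                missing.append(f"{c.name}: needs equation 'cig' or 'ecig'")
                continue
            bad = [a for a in c.attributes if a not in cols]
            if bad:
                missing.append(f"{c.name}: columns {bad}")
            else:
                resolved[c.name] = (c.equation, c.attributes)
    else:
        raise ConfigurationError(f"unsupported dataset type {type(data)!r}")
    if missing:
        raise ConfigurationError("unresolved specification entries: " + "; ".join(missing))
    return SpecReport(n_params=spec.n_params, resolved=resolved, messages=[])


def spec_from_dict(d: Mapping) -> ModelSpec:
    """Build a ModelSpec from a plain dict (YAML/JSON model file contents)."""
    coefs = []
    for cd in d["coefficients"]:
        coefs.append(
            CoefficientSpec(
                name=cd["name"],
                dist=cd.get("dist", "fixed"),
                attributes=tuple(cd.get("attributes", ())),
                sign=int(cd.get("sign", -1)),
                asc_group=cd.get("asc_group"),
                equation=cd.get("equation"),
                fix_offset=bool(cd.get("fix_offset", True)),
            )
        )
    return ModelSpec(
        coefficients=tuple(coefs),
        space=d.get("space", "preference"),
        price_coefficient=d.get("price_coefficient"),
        rp_error_component=d.get("rp_error_component"),
    )


def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "space": spec.space,
        "price_coefficient": spec.price_coefficient,
        "rp_error_component": dict(spec.rp_error_component)
        if spec.rp_error_component
        else None,
        "coefficients": [
            {
                "name": c.name,
                "dist": c.dist,
                "attributes": list(c.attributes),
                "sign": c.sign,
                "asc_group": c.asc_group,
                "equation": c.equation,
                "fix_offset": c.fix_offset,
            }
            for c in spec.coefficients
        ],
    }
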