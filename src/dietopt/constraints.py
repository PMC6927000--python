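"""Constraint construction: RNI nutrient bounds, MDG food-group serving
bounds, per-item caps, portion granularity, and supplement scenarios.

The diet problem is the classical least-cost diet program with integer
portions::

    min  p = sum_j c_j x_j
    s.t. l_i <= sum_j a_ij x_j <= u_i      (nutrients, per RNI)
         L_g <= sum_{j in g} x_j <= U_g    (food groups, per MDG + palatability)
         0 <= x_j <= cap_j                 (per-item repetition caps)
         x_j a multiple of the granularity (integer half-servings by default)

A supplement scenario provides nutrient amounts exogenously and relaxes the
dietary *lower* bounds by those amounts; dietary upper bounds are untouched
(they limit food intake, and supplement regimes such as 100 mg/day iron
deliberately exceed the dietary upper bound of 29 mg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml

from .food_db import ALL_CATEGORIES, FoodCategory, FoodDatabase, FoodItem
from .nutrients import NUTRIENTS, NutrientProfile

#: Valid trimester codes.
TRIMESTERS = (1, 2, 3)

#: Feasibility tolerance on serving units (documented constant).
SERVING_TOL = 1e-6
#: Tolerance for cost comparisons (documented constant).
COST_TOL = 1e-9


@dataclass(frozen=True)
class Bound:
    """A [lower, upper] interval; ``upper=None`` means unbounded above."""

    lower: float = 0.0
    upper: float | None = None

    def __post_init__(self):
        if self.lower < 0:
            raise ValueError(f"negative lower bound {self.lower}")
        if self.upper is not None and self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")

    @property
    def upper_or_inf(self) -> float:
        return math.inf if self.upper is None else self.upper

    def contains(self, value: float, tol: float = SERVING_TOL) -> bool:
        return value >= self.lower - tol and value <= self.upper_or_inf + tol


class NutrientConstraints:
    """One Bound per tracked nutrient (all 15 present)."""

    def __init__(self, bounds: Mapping[str, Bound]):
        missing = [c for c in NUTRIENTS if c not in bounds]
        if missing:
            raise ValueError(f"nutrient bounds missing for {missing}")
        unknown = [c for c in bounds if c not in NUTRIENTS]
        if unknown:
            raise ValueError(f"unknown nutrient code(s) in bounds: {unknown}")
        self._bounds = {c: bounds[c] for c in NUTRIENTS}

    def __getitem__(self, code: str) -> Bound:
        return self._bounds[code]

    def items(self):
        return self._bounds.items()

    def replace(self, **updates: Bound) -> "NutrientConstraints":
        merged = dict(self._bounds)
        merged.update(updates)
        return NutrientConstraints(merged)

    def __eq__(self, other):
        if not isinstance(other, NutrientConstraints):
            return NotImplemented
        return self._bounds == other._bounds

    def __repr__(self):
        return f"NutrientConstraints({self._bounds!r})"


class GroupConstraints:
    """One serving Bound per food category (all 10 present)."""

    def __init__(self, bounds: Mapping[FoodCategory, Bound]):
        missing = [c for c in ALL_CATEGORIES if c not in bounds]
        if missing:
            raise ValueError(f"group bounds missing for {[c.value for c in missing]}")
        self._bounds = {c: bounds[c] for c in ALL_CATEGORIES}

    def __getitem__(self, category: FoodCategory) -> Bound:
        return self._bounds[FoodCategory(category)]

    def items(self):
        return self._bounds.items()

    def replace(self, updates: Mapping[FoodCategory, Bound]) -> "GroupConstraints":
        merged = dict(self._bounds)
        for cat, b in updates.items():
            merged[FoodCategory(cat)] = b
        return GroupConstraints(merged)

    def __eq__(self, other):
        if not isinstance(other, GroupConstraints):
            return NotImplemented
        return self._bounds == other._bounds

    def __repr__(self):
        return f"GroupConstraints({self._bounds!r})"


@dataclass(frozen=True)
class SupplementScenario:
    """Exogenous daily nutrient amounts (e.g. 100 mg elemental iron)."""

    name: str
    provided: NutrientProfile = field(default_factory=NutrientProfile)


@dataclass
class ItemCaps:
    """Per-item serving caps: by-item override > by-category override > default.

    The default cap of 2 servings/day keeps any single food from repeating
    through the menu; fish is capped at 1 serving/day by category (no fish
    dish twice in a day).  All configurable.
    """

    default: float = 2.0
    by_category: dict[FoodCategory, float] = field(
        default_factory=lambda: {FoodCategory.FISH: 1.0}
    )
    by_item: dict[str, float] = field(default_factory=dict)

    def cap_for(self, item: FoodItem) -> float:
        if item.item_id in self.by_item:
            return self.by_item[item.item_id]
        return self.by_category.get(item.category, self.default)


# ---------------------------------------------------------------------------
# Packaged configuration (RNI 2017 / MDG 2010 / supplement defaults)
# ---------------------------------------------------------------------------


def _load_data_yaml(filename: str):
    with resources.files("dietopt.data").joinpath(filename).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def rni_bounds(trimester: int) -> NutrientConstraints:
    """RNI 2017 nutrient bounds for the given pregnancy trimester (1, 2 or 3)."""
    if trimester not in TRIMESTERS:
        raise ValueError(f"trimester must be one of {TRIMESTERS}, got {trimester!r}")
    raw = _load_data_yaml("rni_2017.yaml")[trimester]
    return NutrientConstraints(
        {code: Bound(float(lo), None if hi is None else float(hi))
         for code, (lo, hi) in raw.items()}
    )


@lru_cache(maxsize=None)
def mdg_group_bounds() -> GroupConstraints:
    """MDG 2010 food-group serving bounds plus sugar/salt/oil palatability bounds."""
    raw = _load_data_yaml("mdg_2010.yaml")
    return GroupConstraints(
        {FoodCategory(cat): Bound(float(lo), float(hi)) for cat, (lo, hi) in raw.items()}
    )


def default_supplement_scenario(trimester: int) -> SupplementScenario:
    """Packaged free antenatal supplement regimen for the trimester."""
    if trimester not in TRIMESTERS:
        raise ValueError(f"trimester must be one of {TRIMESTERS}, got {trimester!r}")
    raw = _load_data_yaml("supplements.yaml")[trimester]
    return SupplementScenario(
        name=raw["name"],
        provided=NutrientProfile({k: float(v) for k, v in raw["provided"].items()}),
    )


def apply_supplement(
    nc: NutrientConstraints, scenario: SupplementScenario
) -> NutrientConstraints:
    """Relax dietary lower bounds by exogenously supplied amounts.

    ``new_lower = max(0, lower - provided)``; upper bounds are unchanged.
    Never raises a lower bound; monotone nonincreasing in the supplied
    amounts.
    """
    updates = {}
    for code, bound in nc.items():
        provided = scenario.provided[code]
        if provided > 0 and bound.lower > 0:
            updates[code] = Bound(max(0.0, bound.lower - provided), bound.upper)
    return nc.replace(**updates) if updates else nc


# ---------------------------------------------------------------------------
# Problem specification
# ---------------------------------------------------------------------------


@dataclass
class ProblemSpec:
    """A fully specified integer least-cost diet program.

    Decision variables are integer counts of ``granularity`` servings
    (half-servings by default, so that the 0.5-serving lower bounds on
    meat and legumes are representable while portions stay integral).
    """

    db: FoodDatabase
    nutrient_constraints: NutrientConstraints
    group_constraints: GroupConstraints
    item_caps: ItemCaps = field(default_factory=ItemCaps)
    granularity: float = 0.5

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.granularity <= 0:
            raise ValueError(f"granularity must be positive, got {self.granularity}")
        if len(self.db) == 0:
            raise ValueError("food database is empty")
        for item in self.db:
            cap = self.item_caps.cap_for(item)
            if cap < 0:
                raise ValueError(f"negative cap {cap} for item {item.item_id!r}")
            units = cap / self.granularity
            if abs(units - round(units)) > 1e-9:
                raise ValueError(
                    f"cap {cap} for item {item.item_id!r} is not a multiple "
                    f"of granularity {self.granularity}"
                )

    def cap_units(self) -> list[int]:
        """Per-item variable upper bounds in granularity units, db order."""
        return [
            int(round(self.item_caps.cap_for(item) / self.granularity))
            for item in self.db
        ]

    def with_supplement(self, scenario: SupplementScenario) -> "ProblemSpec":
        return replace(
            self, nutrient_constraints=apply_supplement(self.nutrient_constraints, scenario)
        )


def build_problem(
    db: FoodDatabase,
    trimester: int,
    overrides: Mapping | None = None,
) -> ProblemSpec:
    """Assemble the full diet program for a trimester from packaged defaults.

    ``overrides`` may replace any piece::

        {"granularity": 0.25,
         "nutrient_bounds": {"iron_mg": {"lower": 25, "upper": 29}},
         "group_bounds": {"fish": {"lower": 1, "upper": 2}},
         "item_caps": {"default": 2, "by_category": {"fish": 1},
                       "by_item": {"patin": 1}}}

    Raises
    ------
    ValueError
        If an override produces an inconsistent bound (lower > upper),
        naming the offending constraint.
    """
    overrides = dict(overrides or {})
    nc = rni_bounds(trimester)
    gc = mdg_group_bounds()
    caps = ItemCaps()
    granularity = float(overrides.get("granularity", 0.5))

    for code, spec in dict(overrides.get("nutrient_bounds", {})).items():
        lo, hi = _parse_bound_spec(spec)
        try:
            nc = nc.replace(**{code: Bound(lo, hi)})
        except ValueError as exc:
            raise ValueError(f"inconsistent nutrient bound for {code!r}: {exc}") from exc

    group_updates = {}
    for cat, spec in dict(overrides.get("group_bounds", {})).items():
        lo, hi = _parse_bound_spec(spec)
        try:
            group_updates[FoodCategory(cat)] = Bound(lo, hi)
        except ValueError as exc:
            raise ValueError(f"inconsistent group bound for {cat!r}: {exc}") from exc
    if group_updates:
        gc = gc.replace(group_updates)

    cap_spec = dict(overrides.get("item_caps", {}))
    if cap_spec:
        caps = ItemCaps(
            default=float(cap_spec.get("default", caps.default)),
            by_category={
                FoodCategory(c): float(v)
                for c, v in cap_spec.get(
                    "by_category", {c: v for c, v in caps.by_category.items()}
                ).items()
            },
            by_item={k: float(v) for k, v in cap_spec.get("by_item", {}).items()},
        )

    return ProblemSpec(
        db=db,
        nutrient_constraints=nc,
        group_constraints=gc,
        item_caps=caps,
        granularity=granularity,
    )


def _parse_bound_spec(spec) -> tuple[float, float | None]:
    if isinstance(spec, Bound):
        return spec.lower, spec.upper
    if isinstance(spec, Mapping):
        lo = float(spec.get("lower", 0.0))
        hi = spec.get("upper", None)
        return lo, None if hi is None else float(hi)
    lo, hi = spec  # two-element sequence
    return float(lo), None if hi is None else float(hi)


def load_config(path) -> dict:
    """Read a constraint-override config file (YAML/JSON superset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
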