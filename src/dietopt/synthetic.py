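"""Seeded synthetic food databases, dietary records and test instances.

Real Malaysian food-composition and market-price data are not deposited
anywhere, so every downstream computation is exercised on synthetic
stand-ins with known ground truth.  Per-serving nutrient densities are
log-normal around category-specific medians chosen for the serving
definitions in use (one cereal serving = 30 g carbohydrate, one meat/fish
serving = 14 g protein, one legume/milk serving = 7 g protein, one oil
serving = 9 g fat, one sugar serving = 5 g carbohydrate, one salt serving
~ 1 g NaCl = 390 mg sodium).  Log-normals are positive and heavy-tailed
like real food tables; medians and spreads are packaged below and fully
overridable.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .adequacy import DietaryRecord, SubjectCovariates
from .constraints import (
    Bound,
    GroupConstraints,
    ItemCaps,
    NutrientConstraints,
    ProblemSpec,
    rni_bounds,
)
from .food_db import ALL_CATEGORIES, FoodCategory, FoodDatabase, FoodItem
from .nutrients import NUTRIENTS, NutrientProfile

# ---------------------------------------------------------------------------
# Packaged generator parameters
# ---------------------------------------------------------------------------

#: Median per-serving nutrient amounts by category.  Order-free mapping of
#: nutrient code -> median; omitted nutrients are structural zeros.
DEFAULT_CATEGORY_MEDIANS: dict[FoodCategory, dict[str, float]] = {
    FoodCategory.CEREALS: {
        "energy_kcal": 140, "protein_g": 3.2, "carb_g": 30, "fat_g": 1.0,
        "fibre_g": 2.2, "vitB1_mg": 0.12, "vitB2_mg": 0.05, "vitB3_mg": 1.6,
        "sodium_mg": 5, "potassium_mg": 90, "calcium_mg": 15, "iron_mg": 1.0,
        "phosphorus_mg": 95,
    },
    FoodCategory.FRUITS: {
        "energy_kcal": 60, "protein_g": 0.8, "carb_g": 15, "fat_g": 0.3,
        "fibre_g": 2.5, "vitA_RE": 45, "vitC_mg": 45, "vitB1_mg": 0.05,
        "vitB2_mg": 0.04, "vitB3_mg": 0.5, "sodium_mg": 2, "potassium_mg": 280,
        "calcium_mg": 20, "iron_mg": 0.4, "phosphorus_mg": 25,
    },
    FoodCategory.VEGETABLES: {
        "energy_kcal": 32, "protein_g": 1.9, "carb_g": 5, "fat_g": 0.3,
        "fibre_g": 2.6, "vitA_RE": 260, "vitC_mg": 32, "vitB1_mg": 0.07,
        "vitB2_mg": 0.09, "vitB3_mg": 0.7, "sodium_mg": 22, "potassium_mg": 320,
        "calcium_mg": 65, "iron_mg": 1.3, "phosphorus_mg": 42,
    },
    FoodCategory.MEAT: {
        "energy_kcal": 125, "protein_g": 14, "carb_g": 0.5, "fat_g": 6.5,
        "vitA_RE": 30, "vitC_mg": 0.5, "vitB1_mg": 0.09, "vitB2_mg": 0.16,
        "vitB3_mg": 4.8, "sodium_mg": 60, "potassium_mg": 190, "calcium_mg": 10,
        "iron_mg": 1.6, "phosphorus_mg": 145,
    },
    FoodCategory.FISH: {
        "energy_kcal": 100, "protein_g": 14, "carb_g": 0.5, "fat_g": 4.0,
        "vitA_RE": 16, "vitC_mg": 0.5, "vitB1_mg": 0.06, "vitB2_mg": 0.11,
        "vitB3_mg": 3.8, "sodium_mg": 85, "potassium_mg": 260,
        "calcium_mg": 35, "iron_mg": 1.2, "phosphorus_mg": 165,
    },
    FoodCategory.LEGUMES: {
        "energy_kcal": 110, "protein_g": 7, "carb_g": 15, "fat_g": 1.6,
        "fibre_g": 5.2, "vitA_RE": 2, "vitC_mg": 1.2, "vitB1_mg": 0.18,
        "vitB2_mg": 0.07, "vitB3_mg": 0.8, "sodium_mg": 5, "potassium_mg": 310,
        "calcium_mg": 45, "iron_mg": 2.3, "phosphorus_mg": 125,
    },
    FoodCategory.MILK: {
        "energy_kcal": 130, "protein_g": 7, "carb_g": 10, "fat_g": 7,
        "vitA_RE": 85, "vitC_mg": 2, "vitB1_mg": 0.09, "vitB2_mg": 0.36,
        "vitB3_mg": 0.2, "sodium_mg": 95, "potassium_mg": 340,
        "calcium_mg": 260, "iron_mg": 0.15, "phosphorus_mg": 195,
    },
    FoodCategory.SUGAR: {"energy_kcal": 20, "carb_g": 5},
    FoodCategory.SALT: {"sodium_mg": 390},
    FoodCategory.OIL: {"energy_kcal": 81, "fat_g": 9},
}

#: Median per-serving price (abstract currency) by category.
DEFAULT_PRICE_MEDIANS: dict[FoodCategory, float] = {
    FoodCategory.CEREALS: 0.40,
    FoodCategory.FRUITS: 0.80,
    FoodCategory.VEGETABLES: 0.50,
    FoodCategory.MEAT: 1.50,
    FoodCategory.FISH: 1.20,
    FoodCategory.LEGUMES: 0.60,
    FoodCategory.MILK: 1.00,
    FoodCategory.SUGAR: 0.05,
    FoodCategory.SALT: 0.02,
    FoodCategory.OIL: 0.15,
}

#: Default item counts per category (~200 items total, spanning all 10
#: categories like a trimmed national food table).
DEFAULT_N_ITEMS: dict[FoodCategory, int] = {
    FoodCategory.CEREALS: 35,
    FoodCategory.FRUITS: 30,
    FoodCategory.VEGETABLES: 35,
    FoodCategory.MEAT: 25,
    FoodCategory.FISH: 25,
    FoodCategory.LEGUMES: 18,
    FoodCategory.MILK: 15,
    FoodCategory.SUGAR: 6,
    FoodCategory.SALT: 4,
    FoodCategory.OIL: 7,
}

_CAT_SLUG = {
    FoodCategory.CEREALS: "cereal",
    FoodCategory.FRUITS: "fruit",
    FoodCategory.VEGETABLES: "veg",
    FoodCategory.MEAT: "meat",
    FoodCategory.FISH: "fish",
    FoodCategory.LEGUMES: "legume",
    FoodCategory.MILK: "milk",
    FoodCategory.SUGAR: "sugar",
    FoodCategory.SALT: "salt",
    FoodCategory.OIL: "oil",
}


@dataclass
class GeneratorParams:
    """Parameters of the synthetic food-database generator.

    ``nutrient_sigma`` and ``price_sigma`` are log-scale standard
    deviations of the log-normal draws (dimensionless); medians carry the
    units.  Identical params + seed give identical databases.
    """

    n_items: dict[FoodCategory, int] = field(
        default_factory=lambda: dict(DEFAULT_N_ITEMS)
    )
    category_medians: dict[FoodCategory, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_CATEGORY_MEDIANS.items()}
    )
    price_medians: dict[FoodCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_PRICE_MEDIANS)
    )
    nutrient_sigma: float = 0.35
    price_sigma: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.nutrient_sigma <= 0 or self.price_sigma <= 0:
            raise ValueError("sigma parameters must be positive")


def generate_food_db(params: GeneratorParams | None = None) -> FoodDatabase:
    """Draw a synthetic food database with category-specific densities.

    Raises
    ------
    ValueError
        If every category has zero items.
    """
    params = params or GeneratorParams()
    if sum(params.n_items.get(c, 0) for c in ALL_CATEGORIES) == 0:
        raise ValueError("at least one category must have items")
    rng = np.random.default_rng(params.seed)
    items: list[FoodItem] = []
    for cat in ALL_CATEGORIES:
        n = params.n_items.get(cat, 0)
        medians = params.category_medians.get(cat, {})
        for i in range(n):
            amounts = {
                code: med * math.exp(params.nutrient_sigma * rng.standard_normal())
                for code, med in medians.items()
                if med > 0
            }
            price = params.price_medians.get(cat, 0.5) * math.exp(
                params.price_sigma * rng.standard_normal()
            )
            slug = _CAT_SLUG[cat]
            items.append(
                FoodItem(
                    item_id=f"{slug}_{i:03d}",
                    name=f"synthetic {slug} #{i}",
                    category=cat,
                    profile=NutrientProfile(amounts),
                    price=round(price, 4),
                    serving_note="synthetic",
                )
            )
    return FoodDatabase(items)


def make_iron_scarce(db: FoodDatabase, factor: float) -> FoodDatabase:
    """Scale every item's iron content by ``factor`` in (0, 1]; nothing else
    changes.  Models an iron-poor food supply."""
    if factor <= 0:
        raise ValueError(f"factor must be positive, got {factor}")
    items = []
    for item in db:
        amounts = item.profile.as_dict()
        amounts["iron_mg"] *= factor
        items.append(replace(item, profile=NutrientProfile(amounts)))
    return FoodDatabase(items)


# ---------------------------------------------------------------------------
# Dietary records + covariates
# ---------------------------------------------------------------------------

#: Cohort covariate distribution: mixture weights over Hb classes with the
#: in-class value ranges (g/dL), BMI log-normal moments (kg/m^2) and the
#: gravidity frequency distribution of a suburban antenatal-clinic cohort.
HB_CLASS_WEIGHTS = {"normal": 55 / 78, "mild_anaemia": 17 / 78, "moderate_anaemia": 6 / 78}
HB_CLASS_RANGES = {
    "normal": (11.0, 12.8),
    "mild_anaemia": (10.0, 10.9),
    "moderate_anaemia": (8.3, 9.9),
}
BMI_MEAN, BMI_SD = 24.3, 4.7
GRAVIDITY_WEIGHTS = {1: 17, 2: 19, 3: 20, 4: 10, 5: 7, 6: 4, 7: 1}
TRIMESTER_WEIGHTS = {1: 0.25, 2: 0.52, 3: 0.23}
SUPPLEMENT_USE_RATE = 0.859


def generate_records(
    db: FoodDatabase,
    n_subjects: int = 78,
    n_days: int = 4,
    exceedance_targets: dict[str, float] | None = None,
    seed: int = 0,
    rni: NutrientConstraints | None = None,
) -> tuple[list[DietaryRecord], list[SubjectCovariates]]:
    """Simulate recall/record data (one 24-h recall + a multi-day record).

    When ``exceedance_targets`` maps a nutrient to a fraction f, each
    subject independently achieves the RNI lower bound for that nutrient
    with probability f: an achiever flag is drawn per subject and the
    subject's servings are rescaled so the mean intake lands above or
    below the cut-off by a log-normal margin.  With several simultaneous
    targets only the first is matched exactly in distribution; achieved
    fractions for the rest are reported in a warning when off by more
    than 5 points.

    Covariates are drawn from the packaged cohort distributions (Hb class
    mixture, log-normal BMI, categorical gravidity/trimester, supplement
    use rate).
    """
    if len(db) == 0:
        raise ValueError("food database is empty")
    if n_subjects < 1 or n_days < 1:
        raise ValueError("n_subjects and n_days must be >= 1")
    rni = rni or rni_bounds(2)
    rng = np.random.default_rng(seed)
    n_items = len(db)
    profiles = db.nutrient_matrix()

    records: list[DietaryRecord] = []
    covariates: list[SubjectCovariates] = []
    subject_means: list[np.ndarray] = []

    targets = dict(exceedance_targets or {})
    target_codes = list(targets)
    primary = target_codes[0] if target_codes else None

    for s in range(n_subjects):
        sid = f"S{s:04d}"
        # personal preference weights over items
        pref = rng.dirichlet(np.full(n_items, 0.3))
        day_consumptions: list[dict[int, float]] = []
        for _ in range(n_days):
            k = int(rng.integers(8, 15))
            chosen = rng.choice(n_items, size=min(k, n_items), replace=False, p=None)
            day = {
                int(j): float(rng.choice([0.5, 1.0, 1.0, 1.5, 2.0])) * (1 + 3 * pref[j])
                for j in chosen
            }
            day_consumptions.append(day)

        mean_vec = np.zeros(profiles.shape[1])
        for day in day_consumptions:
            for j, serv in day.items():
                mean_vec += serv * profiles[j]
        mean_vec /= n_days

        scale = 1.0
        if primary is not None:
            cutoff = rni[primary].lower
            idx = NUTRIENTS.index(primary)
            base = mean_vec[idx]
            achiever = rng.random() < targets[primary]
            margin = math.exp(abs(rng.standard_normal()) * 0.25)
            if base <= 0:
                if achiever:
                    warnings.warn(
                        f"subject {sid}: no {primary} in drawn foods; "
                        f"exceedance target unattainable"
                    )
            elif achiever:
                scale = cutoff * margin / base
            else:
                scale = cutoff / (margin * base) * (1 - 1e-9)

        for d, day in enumerate(day_consumptions, start=1):
            consumed = [
                (db.items[j].item_id, round(serv * scale, 6)) for j, serv in day.items()
            ]
            records.append(DietaryRecord(subject_id=sid, day_index=d, consumed=consumed))
        subject_means.append(mean_vec * scale)

        hb_class = rng.choice(list(HB_CLASS_WEIGHTS), p=list(HB_CLASS_WEIGHTS.values()))
        lo, hi = HB_CLASS_RANGES[hb_class]
        hb = float(np.clip(rng.normal((lo + hi) / 2, (hi - lo) / 4), lo, hi))
        log_sd = math.sqrt(math.log(1 + (BMI_SD / BMI_MEAN) ** 2))
        bmi = float(
            np.clip(rng.lognormal(math.log(BMI_MEAN) - log_sd**2 / 2, log_sd), 17.0, 34.9)
        )
        covariates.append(
            SubjectCovariates(
                subject_id=sid,
                hb=round(hb, 2),
                bmi=round(bmi, 2),
                gravidity=int(
                    rng.choice(
                        list(GRAVIDITY_WEIGHTS),
                        p=np.array(list(GRAVIDITY_WEIGHTS.values()))
                        / sum(GRAVIDITY_WEIGHTS.values()),
                    )
                ),
                trimester=int(
                    rng.choice(list(TRIMESTER_WEIGHTS), p=list(TRIMESTER_WEIGHTS.values()))
                ),
                supplement_user=bool(rng.random() < SUPPLEMENT_USE_RATE),
            )
        )

    # report achieved fractions for secondary targets
    if len(target_codes) > 1:
        M = np.vstack(subject_means)
        for code in target_codes[1:]:
            idx = NUTRIENTS.index(code)
            achieved = float(np.mean(M[:, idx] >= rni[code].lower))
            if abs(achieved - targets[code]) > 0.05:
                warnings.warn(
                    f"secondary exceedance target for {code}: requested "
                    f"{targets[code]:.2f}, achieved {achieved:.2f}"
                )
    return records, covariates


# ---------------------------------------------------------------------------
# Optimization test instances with known ground truth
# ---------------------------------------------------------------------------


def generate_small_instance(
    seed: int, n_items: int = 6, max_cap_units: int = 4, granularity: float = 0.5
) -> ProblemSpec:
    """A random small diet program suitable for exhaustive enumeration.

    A handful of items from random categories, a few randomly bounded
    nutrients (lower bounds placed between 20% and 110% of the attainable
    maximum, so a meaningful share of instances is infeasible), relaxed
    group bounds, and small per-item caps.
    """
    rng = np.random.default_rng(seed)
    cats = rng.choice(len(ALL_CATEGORIES), size=n_items, replace=True)
    items = []
    for i, ci in enumerate(cats):
        cat = ALL_CATEGORIES[int(ci)]
        medians = DEFAULT_CATEGORY_MEDIANS.get(cat, {})
        amounts = {
            code: med * math.exp(0.4 * rng.standard_normal())
            for code, med in medians.items()
            if med > 0
        }
        items.append(
            FoodItem(
                item_id=f"it_{i}",
                name=f"instance item {i}",
                category=cat,
                profile=NutrientProfile(amounts),
                price=round(float(rng.uniform(0.05, 2.0)), 4),
            )
        )
    db = FoodDatabase(items)
    cap = max_cap_units * granularity
    caps = ItemCaps(default=cap, by_category={}, by_item={})

    max_attainable = (db.nutrient_matrix() * cap).sum(axis=0)
    n_constrained = int(rng.integers(2, 5))
    constrained = rng.choice(len(NUTRIENTS), size=n_constrained, replace=False)
    bounds = {code: Bound(0.0, None) for code in NUTRIENTS}
    for ci in constrained:
        code = NUTRIENTS[int(ci)]
        attainable = max_attainable[int(ci)]
        if attainable <= 0:
            continue
        lower = float(rng.uniform(0.2, 1.1)) * attainable
        upper = None if rng.random() < 0.5 else lower * float(rng.uniform(1.5, 3.0))
        bounds[code] = Bound(lower, upper)
    nc = NutrientConstraints(bounds)

    group_bounds = {c: Bound(0.0, None) for c in ALL_CATEGORIES}
    present = {item.category for item in items}
    if rng.random() < 0.4 and present:
        cat = sorted(present, key=lambda c: c.value)[int(rng.integers(len(present)))]
        n_in_cat = sum(1 for it in items if it.category == cat)
        group_bounds[cat] = Bound(
            granularity * int(rng.integers(0, 2)),
            granularity * int(rng.integers(2, 2 * n_in_cat * max_cap_units + 2)),
        )
    gc = GroupConstraints(group_bounds)

    return ProblemSpec(
        db=db, nutrient_constraints=nc, group_constraints=gc,
        item_caps=caps, granularity=granularity,
    )


def generate_known_optimum_instance(seed: int, mode: str | None = None):
    """An instance with a provably optimal solution attached.

    Two constructions:

    * ``"pinned"`` — a serving vector s* is drawn, per-item caps are set
      exactly to s* and each group lower bound to the group's total, so
      s* is the *unique* feasible point (caps force x <= s* componentwise
      while the group sums force equality).  Nutrient bounds bracket the
      achieved profile.
    * ``"oracle"`` — a small random instance solved by exhaustive
      enumeration; the enumerated optimum is returned.

    Returns ``(ProblemSpec, DietSolution)``; the solution has status
    "optimal" for pinned instances and whatever the oracle found
    (possibly "infeasible") for oracle instances.
    """
    from .optimizer import brute_force, _build_solution

    rng = np.random.default_rng(seed)
    if mode is None:
        mode = "pinned" if rng.random() < 0.5 else "oracle"

    if mode == "oracle":
        problem = generate_small_instance(seed=int(rng.integers(2**31)))
        return problem, brute_force(problem)

    if mode != "pinned":
        raise ValueError(f"unknown mode {mode!r}")

    granularity = 0.5
    n_items = int(rng.integers(4, 9))
    cats = rng.choice(len(ALL_CATEGORIES), size=n_items, replace=True)
    items = []
    for i, ci in enumerate(cats):
        cat = ALL_CATEGORIES[int(ci)]
        medians = DEFAULT_CATEGORY_MEDIANS.get(cat, {})
        amounts = {
            code: med * math.exp(0.4 * rng.standard_normal())
            for code, med in medians.items()
            if med > 0
        }
        items.append(
            FoodItem(
                item_id=f"pin_{i}",
                name=f"pinned item {i}",
                category=cat,
                profile=NutrientProfile(amounts),
                price=round(float(rng.uniform(0.05, 2.0)), 4),
            )
        )
    db = FoodDatabase(items)
    k_star = rng.integers(0, 5, size=n_items)  # units of half-servings
    s_star = k_star * granularity

    caps = ItemCaps(
        default=0.0, by_category={},
        by_item={item.item_id: float(s) for item, s in zip(items, s_star)},
    )
    group_bounds = {c: Bound(0.0, None) for c in ALL_CATEGORIES}
    for cat in ALL_CATEGORIES:
        total = float(sum(s for item, s in zip(items, s_star) if item.category == cat))
        group_bounds[cat] = Bound(total, total)
    gc = GroupConstraints(group_bounds)

    achieved = (db.nutrient_matrix() * s_star[:, None]).sum(axis=0)
    nc = NutrientConstraints(
        {code: Bound(0.0, float(a) * 1.5 + 1.0) for code, a in zip(NUTRIENTS, achieved)}
    )
    problem = ProblemSpec(
        db=db, nutrient_constraints=nc, group_constraints=gc,
        item_caps=caps, granularity=granularity,
    )
    solution = _build_solution(problem, k_star.astype(int))
    return problem, solution
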