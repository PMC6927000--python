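"""Food items, food categories, the food database and its CSV schema.

A food database is an ordered collection of items, each carrying a
per-serving nutrient profile, a per-serving price and a food category.
The ten categories are the seven food groups of the Malaysian Dietary
Guidelines (cereals and grains, fruits, vegetables, meat/poultry, fish,
legumes, milk and dairy products) plus the three palatability items
(sugar, salt, oil) that make an optimized diet acceptable to eat.

The CSV schema is fixed::

    item_id,name,category,price,serving_note,energy_kcal,protein_g,carb_g,
    fat_g,fibre_g,vitA_RE,vitC_mg,vitB1_mg,vitB2_mg,vitB3_mg,sodium_mg,
    potassium_mg,calcium_mg,iron_mg,phosphorus_mg

UTF-8, decimal point, category spelled exactly as the category codes.
Missing nutrient cells parse as 0 with a logged warning (food composition
tables are routinely sparse); negative values and duplicate ids are hard
errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .nutrients import N_NUTRIENTS, NUTRIENTS, NutrientProfile

logger = logging.getLogger(__name__)


class FoodCategory(str, Enum):
    """The ten food categories: seven MDG food groups + three palatability items."""

    CEREALS = "cereals and grains"
    FRUITS = "fruits"
    VEGETABLES = "vegetables"
    MEAT = "meat/poultry"
    FISH = "fish"
    LEGUMES = "legumes"
    MILK = "milk and dairy products"
    SUGAR = "sugar"
    SALT = "salt"
    OIL = "oil"


#: The seven MDG food groups (serving recommendations apply to these).
MDG_GROUPS: tuple[FoodCategory, ...] = (
    FoodCategory.CEREALS,
    FoodCategory.FRUITS,
    FoodCategory.VEGETABLES,
    FoodCategory.MEAT,
    FoodCategory.FISH,
    FoodCategory.LEGUMES,
    FoodCategory.MILK,
)

#: Palatability additions bounded to customary consumption.
PALATABILITY_GROUPS: tuple[FoodCategory, ...] = (
    FoodCategory.SUGAR,
    FoodCategory.SALT,
    FoodCategory.OIL,
)

ALL_CATEGORIES: tuple[FoodCategory, ...] = MDG_GROUPS + PALATABILITY_GROUPS

CSV_COLUMNS: tuple[str, ...] = (
    "item_id",
    "name",
    "category",
    "price",
    "serving_note",
) + NUTRIENTS


@dataclass
class FoodItem:
    """One candidate food with its per-serving nutrient profile and price."""

    item_id: str
    name: str
    category: FoodCategory
    profile: NutrientProfile
    price: float
    serving_note: str = ""

    def __post_init__(self):
        if self.price < 0:
            raise ValueError(f"item {self.item_id!r}: negative price {self.price}")
        if not isinstance(self.category, FoodCategory):
            self.category = FoodCategory(self.category)


@dataclass
class FoodDatabase:
    """Ordered, id-unique collection of food items.

    The row order is stable and meaningful: it defines the lexicographic
    tie-breaking order used by the optimizer.
    """

    items: list[FoodItem] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise ValueError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
        self._index = {item.item_id: i for i, item in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> FoodItem:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}")

    def index_of(self, item_id: str) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}")

    @property
    def item_ids(self) -> list[str]:
        return [item.item_id for item in self.items]

    def nutrient_matrix(self) -> np.ndarray:
        """(n_items, 15) per-serving nutrient amounts in database order."""
        if not self.items:
            return np.zeros((0, N_NUTRIENTS))
        return np.vstack([item.profile.values for item in self.items])

    def price_vector(self) -> np.ndarray:
        return np.array([item.price for item in self.items], dtype=float)

    def category_indices(self) -> dict[FoodCategory, np.ndarray]:
        """Item positions per category (possibly empty arrays)."""
        out: dict[FoodCategory, list[int]] = {c: [] for c in ALL_CATEGORIES}
        for i, item in enumerate(self.items):
            out[item.category].append(i)
        return {c: np.array(ix, dtype=int) for c, ix in out.items()}

    def subset(self, item_ids: Iterable[str]) -> "FoodDatabase":
        return FoodDatabase([self[i] for i in item_ids])


def read_food_db(path) -> FoodDatabase:
    """Read a food database from CSV, validating the schema.

    Missing nutrient cells become 0 (one warning per affected cell batch);
    duplicate ids, negative amounts or prices, and unknown categories are
    hard errors naming the offender.
    """
    df = pd.read_csv(path, dtype={"item_id": str, "name": str, "serving_note": str})
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"food DB CSV missing required column(s): {missing_cols}")

    dup = df["item_id"][df["item_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate item_id {dup.iloc[0]!r} in food DB")

    items: list[FoodItem] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        amounts = {}
        for code in NUTRIENTS:
            val = rec[code]
            if pd.isna(val):
                logger.warning(
                    "food DB row %d (item %r): blank %s cell treated as 0",
                    row_no, rec["item_id"], code,
                )
                val = 0.0
            if val < 0:
                raise ValueError(
                    f"food DB row {row_no} (item {rec['item_id']!r}): "
                    f"negative {code} = {val}"
                )
            amounts[code] = float(val)
        price = rec["price"]
        if pd.isna(price) or price < 0:
            raise ValueError(
                f"food DB row {row_no} (item {rec['item_id']!r}): "
                f"missing or negative price {price}"
            )
        try:
            category = FoodCategory(rec["category"])
        except ValueError:
            raise ValueError(
                f"food DB row {row_no} (item {rec['item_id']!r}): "
                f"unknown category {rec['category']!r}; "
                f"valid: {[c.value for c in ALL_CATEGORIES]}"
            )
        note = rec["serving_note"]
        items.append(
            FoodItem(
                item_id=rec["item_id"],
                name=rec["name"],
                category=category,
                profile=NutrientProfile(amounts),
                price=float(price),
                serving_note="" if pd.isna(note) else str(note),
            )
        )
    return FoodDatabase(items)


def write_food_db(db: FoodDatabase, path) -> None:
    """Write a food database to CSV; ``read_food_db`` round-trips it exactly."""
    rows = []
    for item in db:
        rec = {
            "item_id": item.item_id,
            "name": item.name,
            "category": item.category.value,
            "price": item.price,
            "serving_note": item.serving_note,
        }
        rec.update(item.profile.as_dict())
        rows.append(rec)
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def evaluate_servings(
    servings: Mapping[str, float], db: FoodDatabase
) -> tuple[NutrientProfile, float]:
    """Total nutrient profile and cost of a serving assignment.

    Pure linear accounting: profile = sum_j servings_j * profile_j and
    cost = sum_j servings_j * price_j.  Every module that needs nutrient
    totals (the optimizer's feasibility re-check, the adequacy statistics,
    the menu totals) routes through here.

    Raises
    ------
    KeyError
        If a serving refers to an item_id not in ``db``.
    ValueError
        If any serving count is negative.
    """
    total = np.zeros(N_NUTRIENTS)
    cost = 0.0
    for item_id, n in servings.items():
        item = db[item_id]  # raises KeyError naming the id
        if n < 0:
            raise ValueError(f"negative servings {n} for item {item_id!r}")
        total += n * item.profile.values
        cost += n * item.price
    return NutrientProfile(total), float(cost)
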