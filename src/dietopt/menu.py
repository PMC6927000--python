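"""Arrange an optimized serving vector into a one-day menu.

Five meal slots (breakfast, morning tea, lunch, afternoon tea, dinner).
Staple categories go to the three main meals; fruits, milk and sugar fill
the tea breaks first.  Slotting is deterministic cosmetic plumbing over a
solved diet — the nutrition lives entirely in the serving vector, and the
menu conserves it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .food_db import FoodCategory, FoodDatabase, evaluate_servings
from .nutrients import NutrientProfile
from .optimizer import DietSolution


class MealSlot(str, Enum):
    BREAKFAST = "breakfast"
    MORNING_TEA = "morning_tea"
    LUNCH = "lunch"
    AFTERNOON_TEA = "afternoon_tea"
    DINNER = "dinner"


SLOT_ORDER: tuple[MealSlot, ...] = (
    MealSlot.BREAKFAST,
    MealSlot.MORNING_TEA,
    MealSlot.LUNCH,
    MealSlot.AFTERNOON_TEA,
    MealSlot.DINNER,
)

MAIN_MEALS: tuple[MealSlot, ...] = (MealSlot.BREAKFAST, MealSlot.LUNCH, MealSlot.DINNER)
TEA_BREAKS: tuple[MealSlot, ...] = (MealSlot.MORNING_TEA, MealSlot.AFTERNOON_TEA)

#: Categories served at main meals only.
STAPLE_CATEGORIES: frozenset[FoodCategory] = frozenset(
    {
        FoodCategory.CEREALS,
        FoodCategory.MEAT,
        FoodCategory.FISH,
        FoodCategory.VEGETABLES,
        FoodCategory.LEGUMES,
        FoodCategory.OIL,
        FoodCategory.SALT,
    }
)


@dataclass
class SlottingRules:
    """How servings spread over slots.

    ``per_slot_max`` caps how much of one item a single slot may hold; an
    item never appears twice in the same slot, so an item with 2 servings
    under the default cap of 1 serving/slot lands in two different meals
    (no identical dish repeated within a meal, limited repetition across
    the day).
    """

    per_slot_max: float = 1.0


@dataclass
class DayMenu:
    """Per-slot item servings plus conserved nutrient and cost totals."""

    slots: dict[MealSlot, list[tuple[str, float]]] = field(
        default_factory=lambda: {s: [] for s in SLOT_ORDER}
    )
    totals: NutrientProfile = field(default_factory=NutrientProfile)
    total_cost: float = 0.0

    def servings_by_item(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for entries in self.slots.values():
            for item_id, s in entries:
                out[item_id] = out.get(item_id, 0.0) + s
        return out


def assemble(
    solution: DietSolution, db: FoodDatabase, rules: SlottingRules | None = None
) -> DayMenu:
    """Deterministically allocate an optimal serving vector to meal slots.

    Staples rotate through breakfast/lunch/dinner; fruits, milk and sugar
    rotate through the tea breaks first, spilling into main meals when the
    breaks are full.  Conservation is exact: the slot-wise union equals the
    input serving vector item by item.

    Raises
    ------
    ValueError
        If an item's servings exceed what its eligible slots can hold
        (suggesting a lower item cap or a higher per-slot allowance).
    """
    if not solution.is_optimal:
        raise ValueError("assemble requires an optimal solution")
    rules = rules or SlottingRules()
    menu = DayMenu()
    used: dict[tuple[str, MealSlot], float] = {}
    rotation = {True: 0, False: 0}  # separate round-robin cursors

    for item in db:  # db order => determinism
        remaining = solution.servings.get(item.item_id, 0.0)
        if remaining <= 0:
            continue
        staple = item.category in STAPLE_CATEGORIES
        eligible = MAIN_MEALS if staple else TEA_BREAKS + MAIN_MEALS
        capacity = rules.per_slot_max * len(eligible)
        if remaining > capacity + 1e-9:
            raise ValueError(
                f"item {item.item_id!r} has {remaining} servings but its "
                f"{len(eligible)} eligible slots hold at most {capacity}; "
                f"lower the item cap or raise per_slot_max"
            )
        cursor = rotation[staple]
        attempts = 0
        while remaining > 1e-12 and attempts < 2 * len(eligible):
            slot = eligible[cursor % len(eligible)]
            cursor += 1
            attempts += 1
            already = used.get((item.item_id, slot), 0.0)
            room = rules.per_slot_max - already
            if room <= 1e-12:
                continue
            portion = min(remaining, room)
            menu.slots[slot].append((item.item_id, portion))
            used[(item.item_id, slot)] = already + portion
            remaining -= portion
        rotation[staple] = cursor

    menu.totals, menu.total_cost = evaluate_servings(menu.servings_by_item(), db)
    return menu


def render_menu(menu: DayMenu, db: FoodDatabase, markdown: bool = False) -> str:
    """Render a day menu slot by slot with nutrient totals and the cost line."""
    lines: list[str] = []
    h = (lambda s: f"## {s}") if markdown else (lambda s: s.upper())
    bullet = "- " if markdown else "  "
    for slot in SLOT_ORDER:
        lines.append(h(slot.value.replace("_", " ").title()))
        entries = menu.slots[slot]
        if not entries:
            lines.append(f"{bullet}(nothing)")
        for item_id, s in entries:
            name = db[item_id].name if item_id in db else item_id
            lines.append(f"{bullet}{name} x {s:g} serving(s)")
        lines.append("")
    lines.append(h("Daily Totals"))
    for code, amount in menu.totals.as_dict().items():
        lines.append(f"{bullet}{code}: {amount:.1f}")
    lines.append("")
    lines.append(f"Food Cost Per Day: {menu.total_cost:.2f}")
    return "\n".join(lines)
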