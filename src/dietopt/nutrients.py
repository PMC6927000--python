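"""The tracked nutrient panel and per-serving nutrient arithmetic.

The package tracks a closed panel of 15 quantities: energy, the three
macronutrients, fibre, five vitamins (A, C, B1, B2, B3) and five minerals
(sodium, potassium, calcium, iron, phosphorus).  Folate, vitamin D and
individual fatty acids are deliberately outside the panel.  Each nutrient
has one canonical unit; all amounts are per serving unless stated
otherwise.
"""

from __future__ import annotations

from typing import Iterator, Mapping

import numpy as np

#: Canonical nutrient codes, in fixed panel order.  These double as the
#: nutrient column names of the food-database CSV schema.
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "carb_g",
    "fat_g",
    "fibre_g",
    "vitA_RE",
    "vitC_mg",
    "vitB1_mg",
    "vitB2_mg",
    "vitB3_mg",
    "sodium_mg",
    "potassium_mg",
    "calcium_mg",
    "iron_mg",
    "phosphorus_mg",
)

#: Canonical unit per nutrient code.
UNITS: dict[str, str] = {
    "energy_kcal": "kcal",
    "protein_g": "g",
    "carb_g": "g",
    "fat_g": "g",
    "fibre_g": "g",
    "vitA_RE": "RE",
    "vitC_mg": "mg",
    "vitB1_mg": "mg",
    "vitB2_mg": "mg",
    "vitB3_mg": "mg",
    "sodium_mg": "mg",
    "potassium_mg": "mg",
    "calcium_mg": "mg",
    "iron_mg": "mg",
    "phosphorus_mg": "mg",
}

_INDEX: dict[str, int] = {code: i for i, code in enumerate(NUTRIENTS)}

N_NUTRIENTS = len(NUTRIENTS)


def nutrient_index(code: str) -> int:
    """Position of ``code`` in the fixed panel order.

    Raises
    ------
    KeyError
        If ``code`` is not one of the 15 tracked nutrients.
    """
    try:
        return _INDEX[code]
    except KeyError:
        raise KeyError(f"unknown nutrient code {code!r}; tracked panel: {NUTRIENTS}")


class NutrientProfile:
    """A vector of nutrient amounts over the fixed 15-nutrient panel.

    Supports componentwise addition and nonnegative scalar multiplication,
    which is all the linear accounting the diet model needs.  Amounts for
    nutrients not supplied default to zero; negative amounts are rejected.

    Parameters
    ----------
    amounts
        Mapping of nutrient code to amount (missing codes = 0), or an
        array of length 15 in panel order.
    """

    __slots__ = ("_v",)

    def __init__(self, amounts: Mapping[str, float] | np.ndarray | None = None):
        if amounts is None:
            v = np.zeros(N_NUTRIENTS)
        elif isinstance(amounts, np.ndarray):
            if amounts.shape != (N_NUTRIENTS,):
                raise ValueError(
                    f"expected array of shape ({N_NUTRIENTS},), got {amounts.shape}"
                )
            v = amounts.astype(float, copy=True)
        else:
            v = np.zeros(N_NUTRIENTS)
            for code, amount in amounts.items():
                v[nutrient_index(code)] = float(amount)
        if np.any(v < 0):
            bad = [NUTRIENTS[i] for i in np.flatnonzero(v < 0)]
            raise ValueError(f"negative nutrient amount(s) for {bad}")
        self._v = v

    # -- accessors ---------------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        """Amounts as a read-only array in panel order."""
        out = self._v.view()
        out.flags.writeable = False
        return out

    def __getitem__(self, code: str) -> float:
        return float(self._v[nutrient_index(code)])

    def as_dict(self) -> dict[str, float]:
        return {code: float(self._v[i]) for i, code in enumerate(NUTRIENTS)}

    def __iter__(self) -> Iterator[str]:
        return iter(NUTRIENTS)

    # -- linear algebra ----------------------------------------------------

    def __add__(self, other: "NutrientProfile") -> "NutrientProfile":
        if not isinstance(other, NutrientProfile):
            return NotImplemented
        return NutrientProfile(self._v + other._v)

    def __mul__(self, scalar: float) -> "NutrientProfile":
        if scalar < 0:
            raise ValueError("nutrient profiles cannot be scaled by a negative factor")
        return NutrientProfile(self._v * float(scalar))

    __rmul__ = __mul__

    # -- comparison --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientProfile):
            return NotImplemented
        return bool(np.array_equal(self._v, other._v))

    def __hash__(self):  # profiles are mutable-array backed; not hashable
        raise TypeError("NutrientProfile is unhashable")

    def allclose(self, other: "NutrientProfile", rtol: float = 1e-9, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self._v, other._v, rtol=rtol, atol=atol))

    def __repr__(self) -> str:
        nonzero = {c: round(v, 4) for c, v in self.as_dict().items() if v}
        return f"NutrientProfile({nonzero})"
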