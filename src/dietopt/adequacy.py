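"""Dietary-assessment statistics for a cohort of pregnant women.

From recall/record data (per subject, per day, item servings) this module
computes mean daily nutrient intakes, the percentage of subjects achieving
the RNI for each nutrient, macronutrient energy contributions (Atwater
4/4/9 kcal/g), and descriptive summaries of haemoglobin, BMI and gravidity.

Endpoint conventions: printed category ranges like "10-10.9 g/dL" are
half-open intervals [10.0, 11.0) so that adjacent classes tile the scale;
anaemia in pregnancy is Hb < 11 g/dL; BMI classes use the Asian cut-points
(underweight < 18.5, normal 18.5-22.9, overweight 23-27.4, pre-obese
27.5-34.9 kg/m^2).  Reported percentages are rounded half-up to one
decimal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constraints import NutrientConstraints
from .food_db import FoodDatabase, evaluate_servings
from .nutrients import NUTRIENTS, NutrientProfile

#: Atwater energy conversion factors, kcal per gram.
ATWATER_KCAL_PER_G = {"carb_g": 4.0, "protein_g": 4.0, "fat_g": 9.0}

HB_CATEGORIES = ("normal", "mild_anaemia", "moderate_anaemia", "out_of_range")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "preobese", "out_of_range")


@dataclass
class DietaryRecord:
    """One day of recalled/recorded intake for one subject."""

    subject_id: str
    day_index: int
    consumed: list[tuple[str, float]]

    def __post_init__(self):
        if self.day_index < 1:
            raise ValueError(f"day_index must be positive, got {self.day_index}")
        for item_id, s in self.consumed:
            if s < 0:
                raise ValueError(
                    f"subject {self.subject_id} day {self.day_index}: "
                    f"negative servings for {item_id!r}"
                )


@dataclass
class SubjectCovariates:
    subject_id: str
    hb: float  # g/dL
    bmi: float  # kg/m^2
    gravidity: int
    trimester: int
    supplement_user: bool

    def __post_init__(self):
        if self.hb <= 0 or self.bmi <= 0:
            raise ValueError(f"subject {self.subject_id}: hb and bmi must be positive")
        if self.gravidity < 1:
            raise ValueError(f"subject {self.subject_id}: gravidity must be >= 1")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_hb(hb: float) -> str:
    """Haemoglobin class: normal [11,16], mild [10,11), moderate [8,10)."""
    if hb <= 0:
        raise ValueError(f"hb must be positive, got {hb}")
    if 11.0 <= hb <= 16.0:
        return "normal"
    if 10.0 <= hb < 11.0:
        return "mild_anaemia"
    if 8.0 <= hb < 10.0:
        return "moderate_anaemia"
    return "out_of_range"


def classify_bmi(bmi: float) -> str:
    """BMI class at Asian cut-points; values >= 35 are out of range."""
    if bmi <= 0:
        raise ValueError(f"bmi must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 23.0:
        return "normal"
    if bmi < 27.5:
        return "overweight"
    if bmi < 35.0:
        return "preobese"
    return "out_of_range"


def subject_mean_intake(
    records: Iterable[DietaryRecord], db: FoodDatabase
) -> NutrientProfile:
    """Mean daily nutrient profile over a subject's recorded days
    (equal weight per day)."""
    records = list(records)
    if not records:
        raise ValueError("at least one day of records is required")
    total = np.zeros(len(NUTRIENTS))
    for rec in records:
        profile, _ = evaluate_servings(dict_sum(rec.consumed), db)
        total += profile.values
    return NutrientProfile(total / len(records))


def dict_sum(pairs: Iterable[tuple[str, float]]) -> dict[str, float]:
    """Collapse repeated (item, servings) pairs into per-item totals."""
    out: dict[str, float] = {}
    for item_id, s in pairs:
        out[item_id] = out.get(item_id, 0.0) + s
    return out


def percent_achieving_rni(
    intakes: Mapping[str, NutrientProfile] | Sequence[NutrientProfile],
    rni: NutrientConstraints,
    threshold_fraction: float = 1.0,
) -> dict[str, float]:
    """Percentage of subjects whose mean intake meets the RNI lower bound.

    Achievement is inclusive: intake >= threshold_fraction * lower bound.
    Returned percentages are rounded half-up to one decimal.
    """
    profiles = list(intakes.values()) if isinstance(intakes, Mapping) else list(intakes)
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    out = {}
    for code in NUTRIENTS:
        cutoff = threshold_fraction * rni[code].lower
        achieved = sum(1 for p in profiles if p[code] >= cutoff)
        out[code] = round_half_up(100.0 * achieved / n)
    return out


def energy_percent(profile: NutrientProfile) -> tuple[float, float, float]:
    """(carbohydrate%, protein%, fat%) of energy, by Atwater 4/4/9 factors."""
    energy = profile["energy_kcal"]
    if energy <= 0:
        raise ValueError("energy_percent requires positive energy")
    return (
        100.0 * ATWATER_KCAL_PER_G["carb_g"] * profile["carb_g"] / energy,
        100.0 * ATWATER_KCAL_PER_G["protein_g"] * profile["protein_g"] / energy,
        100.0 * ATWATER_KCAL_PER_G["fat_g"] * profile["fat_g"] / energy,
    )


def category_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Counts -> percentages of the total, rounded half-up to one decimal."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no observations")
    return {k: round_half_up(100.0 * v / total) for k, v in counts.items()}


def mean_gravidity_from_counts(counts: Mapping[int, int]) -> float:
    """Weighted mean number of pregnancies from a gravidity frequency table."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no observations")
    return sum(g * c for g, c in counts.items()) / n


def anaemic_percent_from_hb_counts(counts: Mapping[str, int]) -> float:
    """Percent of subjects with Hb < 11 g/dL (mild + moderate classes)."""
    total = sum(counts.values())
    anaemic = counts.get("mild_anaemia", 0) + counts.get("moderate_anaemia", 0)
    if total == 0:
        raise ValueError("no observations")
    return round_half_up(100.0 * anaemic / total)


@dataclass
class CohortSummary:
    """Descriptive and adequacy statistics for a cohort."""

    n_subjects: int
    intake_mean: dict[str, float]
    intake_sd: dict[str, float | None]  # None when n < 2
    percent_achieving: dict[str, float]
    energy_percent_mean: dict[str, float]  # cho/protein/fat
    hb_counts: dict[str, int]
    hb_percent: dict[str, float]
    bmi_counts: dict[str, int]
    bmi_percent: dict[str, float]
    gravidity_counts: dict[int, int]
    gravidity_mean: float | None
    anaemic_percent: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in NUTRIENTS:
            rows.append(
                {
                    "nutrient": code,
                    "mean_intake": self.intake_mean[code],
                    "sd_intake": self.intake_sd[code],
                    "percent_achieving_rni": self.percent_achieving[code],
                }
            )
        return pd.DataFrame(rows).set_index("nutrient")


def cohort_summary(
    records: Iterable[DietaryRecord],
    covariates: Iterable[SubjectCovariates],
    db: FoodDatabase,
    rni: NutrientConstraints,
) -> CohortSummary:
    """Assemble the full cohort summary from records and covariates.

    Subjects with records but no covariates enter the intake/adequacy
    statistics but are excluded (with a warning) from the Hb/BMI/gravidity
    summaries.
    """
    by_subject: dict[str, list[DietaryRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    if not by_subject:
        raise ValueError("no dietary records supplied")

    intakes = {
        sid: subject_mean_intake(recs, db) for sid, recs in by_subject.items()
    }
    n = len(intakes)
    M = np.vstack([p.values for p in intakes.values()])
    intake_mean = {c: float(M[:, i].mean()) for i, c in enumerate(NUTRIENTS)}
    intake_sd = {
        c: (float(M[:, i].std(ddof=1)) if n > 1 else None)
        for i, c in enumerate(NUTRIENTS)
    }
    pct = percent_achieving_rni(intakes, rni)

    ep = np.array([energy_percent(p) for p in intakes.values()])
    energy_percent_mean = {
        "carb": float(ep[:, 0].mean()),
        "protein": float(ep[:, 1].mean()),
        "fat": float(ep[:, 2].mean()),
    }

    cov_map = {c.subject_id: c for c in covariates}
    missing = sorted(set(by_subject) - set(cov_map))
    if missing:
        warnings.warn(
            f"{len(missing)} subject(s) with records lack covariates and are "
            f"excluded from covariate summaries: {missing[:5]}"
        )
    covs = [cov_map[s] for s in by_subject if s in cov_map]

    hb_counts = {k: 0 for k in HB_CATEGORIES}
    bmi_counts = {k: 0 for k in BMI_CATEGORIES}
    grav_counts: dict[int, int] = {}
    for c in covs:
        hb_counts[classify_hb(c.hb)] += 1
        bmi_counts[classify_bmi(c.bmi)] += 1
        grav_counts[c.gravidity] = grav_counts.get(c.gravidity, 0) + 1

    return CohortSummary(
        n_subjects=n,
        intake_mean=intake_mean,
        intake_sd=intake_sd,
        percent_achieving=pct,
        energy_percent_mean=energy_percent_mean,
        hb_counts=hb_counts,
        hb_percent=category_percentages(hb_counts) if covs else {},
        bmi_counts=bmi_counts,
        bmi_percent=category_percentages(bmi_counts) if covs else {},
        gravidity_counts=dict(sorted(grav_counts.items())),
        gravidity_mean=mean_gravidity_from_counts(grav_counts) if covs else None,
        anaemic_percent=anaemic_percent_from_hb_counts(hb_counts) if covs else None,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_records(path) -> list[DietaryRecord]:
    """Read recall/record CSV: ``subject_id,day_index,item_id,servings``."""
    df = pd.read_csv(path, dtype={"subject_id": str, "item_id": str})
    needed = {"subject_id", "day_index", "item_id", "servings"}
    if not needed.issubset(df.columns):
        raise ValueError(f"records CSV missing column(s): {sorted(needed - set(df.columns))}")
    out = []
    for (sid, day), grp in df.groupby(["subject_id", "day_index"], sort=False):
        out.append(
            DietaryRecord(
                subject_id=sid,
                day_index=int(day),
                consumed=list(zip(grp["item_id"], grp["servings"].astype(float))),
            )
        )
    return out


def write_records(records: Iterable[DietaryRecord], path) -> None:
    rows = [
        {"subject_id": r.subject_id, "day_index": r.day_index, "item_id": i, "servings": s}
        for r in records
        for i, s in r.consumed
    ]
    pd.DataFrame(rows, columns=["subject_id", "day_index", "item_id", "servings"]).to_csv(
        path, index=False
    )


def read_covariates(path) -> list[SubjectCovariates]:
    """Read covariates CSV: ``subject_id,hb,bmi,gravidity,trimester,supplement_user``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    needed = {"subject_id", "hb", "bmi", "gravidity", "trimester", "supplement_user"}
    if not needed.issubset(df.columns):
        raise ValueError(f"covariates CSV missing column(s): {sorted(needed - set(df.columns))}")
    return [
        SubjectCovariates(
            subject_id=row.subject_id,
            hb=float(row.hb),
            bmi=float(row.bmi),
            gravidity=int(row.gravidity),
            trimester=int(row.trimester),
            supplement_user=bool(row.supplement_user),
        )
        for row in df.itertuples(index=False)
    ]


def write_covariates(covariates: Iterable[SubjectCovariates], path) -> None:
    rows = [
        {
            "subject_id": c.subject_id,
            "hb": c.hb,
            "bmi": c.bmi,
            "gravidity": c.gravidity,
            "trimester": c.trimester,
            "supplement_user": c.supplement_user,
        }
        for c in covariates
    ]
    pd.DataFrame(
        rows,
        columns=["subject_id", "hb", "bmi", "gravidity", "trimester", "supplement_user"],
    ).to_csv(path, index=False)
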