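"""Exact integer least-cost diet optimization and its diagnostics.

The solver is branch-and-bound over the continuous relaxation (HiGHS via
:func:`scipy.optimize.milp`) with a zero MIP gap, so the returned optimum
is global, not heuristic.  Determinism among equal-cost optima is enforced
by a lexicographic refinement: subject to cost <= c* + 1e-9, each serving
variable is minimized in database order and fixed.  ``brute_force`` is an
independent exhaustive-enumeration oracle with the identical contract,
used to cross-check the solver on small instances.

Tolerances (documented constants): integer feasibility 1e-6 serving units,
cost comparisons 1e-9 currency units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds as VarBounds
from scipy.optimize import LinearConstraint, milp

from .constraints import (
    COST_TOL,
    SERVING_TOL,
    ProblemSpec,
    SupplementScenario,
    build_problem,
)
from .food_db import ALL_CATEGORIES, FoodCategory, FoodDatabase, evaluate_servings
from .nutrients import NUTRIENTS, NutrientProfile

BRUTE_FORCE_GUARD = 10**7
_ENUM_CHUNK = 1 << 17


@dataclass
class DietSolution:
    """Optimizer output: servings per item, cost, achieved nutrients, status."""

    status: str  # "optimal" | "infeasible"
    servings: dict[str, float] = field(default_factory=dict)
    total_cost: float = math.nan
    achieved: NutrientProfile | None = None
    group_servings: dict[FoodCategory, float] = field(default_factory=dict)

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def serving_vector(self, db: FoodDatabase) -> np.ndarray:
        """Servings as a dense vector in database order (zeros included)."""
        v = np.zeros(len(db))
        for item_id, s in self.servings.items():
            v[db.index_of(item_id)] = s
        return v

    def to_dict(self) -> dict:
        out = {
            "status": self.status,
            "total_cost": None if math.isnan(self.total_cost) else self.total_cost,
            "servings": dict(self.servings),
            "achieved": self.achieved.as_dict() if self.achieved else None,
            "group_servings": {c.value: s for c, s in self.group_servings.items()},
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


@dataclass(frozen=True)
class ConstraintStatus:
    """Position of one achieved value relative to its bound interval."""

    name: str
    kind: str  # "nutrient" | "group"
    value: float
    lower: float
    upper: float | None
    side: str  # "lower" | "upper" | "none"
    slack_lower: float
    slack_upper: float  # inf when unbounded above
    relative_position: float | None  # (value-LB)/(UB-LB), both bounds finite


class BindingReport(dict):
    """Mapping constraint name -> :class:`ConstraintStatus` with summaries."""

    def at_lower(self) -> list[str]:
        return [k for k, v in self.items() if v.side == "lower"]

    def at_upper(self) -> list[str]:
        return [k for k, v in self.items() if v.side == "upper"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([v.__dict__ for v in self.values()]).set_index("name")


@dataclass
class InfeasibilityDiagnosis:
    """Single-constraint relaxations that restore feasibility.

    ``culprit_constraints`` lists constraint identifiers (e.g.
    ``"iron_mg:lower"``, ``"cereals and grains:upper"``) whose individual
    removal makes the program feasible; ``irreducible`` is set when no
    single relaxation suffices.
    """

    culprit_constraints: list[str]
    irreducible: bool


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------


def _assemble(problem: ProblemSpec):
    """Constraint matrix over integer unit variables k_j (x_j = k_j * g)."""
    g = problem.granularity
    A_nut = problem.db.nutrient_matrix().T * g  # (15, n)
    cat_ix = problem.db.category_indices()
    n = len(problem.db)
    A_grp = np.zeros((len(ALL_CATEGORIES), n))
    for r, cat in enumerate(ALL_CATEGORIES):
        A_grp[r, cat_ix[cat]] = g

    rows = np.vstack([A_nut, A_grp])
    names: list[tuple[str, str]] = [("nutrient", c) for c in NUTRIENTS] + [
        ("group", c.value) for c in ALL_CATEGORIES
    ]
    lb = np.empty(len(names))
    ub = np.empty(len(names))
    for i, code in enumerate(NUTRIENTS):
        b = problem.nutrient_constraints[code]
        lb[i], ub[i] = b.lower, b.upper_or_inf
    for r, cat in enumerate(ALL_CATEGORIES):
        b = problem.group_constraints[cat]
        lb[len(NUTRIENTS) + r], ub[len(NUTRIENTS) + r] = b.lower, b.upper_or_inf

    cost = problem.db.price_vector() * g
    cap_units = np.array(problem.cap_units(), dtype=float)
    return rows, lb, ub, cost, cap_units, names


def _solve_milp(rows, lb, ub, cost, cap_units, fixed: dict[int, int] | None = None):
    """One HiGHS MILP solve; returns integer unit vector or None if infeasible."""
    n = len(cost)
    var_lb = np.zeros(n)
    var_ub = cap_units.copy()
    if fixed:
        for j, k in fixed.items():
            var_lb[j] = var_ub[j] = k
    res = milp(
        c=cost,
        constraints=LinearConstraint(rows, lb, ub),
        integrality=np.ones(n),
        bounds=VarBounds(var_lb, var_ub),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0:
        return None
    return np.round(res.x).astype(int)


def _build_solution(problem: ProblemSpec, k: np.ndarray) -> DietSolution:
    g = problem.granularity
    servings = {
        item.item_id: int(kj) * g
        for item, kj in zip(problem.db, k)
        if kj > 0
    }
    achieved, total_cost = evaluate_servings(servings, problem.db)
    cat_ix = problem.db.category_indices()
    x = k.astype(float) * g
    group_servings = {cat: float(x[ix].sum()) for cat, ix in cat_ix.items()}
    return DietSolution(
        status="optimal",
        servings=servings,
        total_cost=total_cost,
        achieved=achieved,
        group_servings=group_servings,
    )


# ---------------------------------------------------------------------------
# Exact optimization
# ---------------------------------------------------------------------------


def optimize(problem: ProblemSpec, refine_ties: bool = True) -> DietSolution:
    """Solve the integer least-cost diet program to global optimality.

    With ``refine_ties`` (default), the returned serving vector is the
    lexicographically smallest, in database item order, among all optima
    whose cost is within 1e-9 of the minimum — making the result fully
    deterministic and reproducible across runs and solvers.  Disabling the
    refinement saves one MILP solve per item and is appropriate when only
    status and cost matter (scenario sweeps, infeasibility probing).
    """
    rows, lb, ub, cost, cap_units, _ = _assemble(problem)
    if not np.all(np.isfinite(cap_units)):
        raise ValueError("every item must have a finite serving cap")

    k = _solve_milp(rows, lb, ub, cost, cap_units)
    if k is None:
        return DietSolution(status="infeasible")

    if refine_ties:
        k = _lexicographic_refine(rows, lb, ub, cost, cap_units, k)
    return _build_solution(problem, k)


def _lexicographic_refine(rows, lb, ub, cost, cap_units, k0: np.ndarray) -> np.ndarray:
    """Among cost-minimal solutions, pick the lexicographically smallest."""
    c_star = float(cost @ k0)
    n = len(cost)
    # extra constraint row: total cost capped at the optimum
    rows_c = np.vstack([rows, cost])
    lb_c = np.append(lb, -np.inf)
    ub_c = np.append(ub, c_star + COST_TOL)
    fixed: dict[int, int] = {}
    k = k0
    unit = np.zeros(n)
    for j in range(n):
        if k[j] == 0:
            fixed[j] = 0  # already minimal for this coordinate
            continue
        unit[:] = 0.0
        unit[j] = 1.0
        res = milp(
            c=unit,
            constraints=LinearConstraint(rows_c, lb_c, ub_c),
            integrality=np.ones(n),
            bounds=VarBounds(
                np.array([fixed.get(i, 0) for i in range(n)], dtype=float),
                np.array(
                    [fixed.get(i, cap_units[i]) for i in range(n)], dtype=float
                ),
            ),
            options={"mip_rel_gap": 0.0},
        )
        if res is None or res.status != 0:  # numerical hiccup: keep incumbent
            fixed[j] = int(k[j])
            continue
        kk = np.round(res.x).astype(int)
        if float(cost @ kk) <= c_star + COST_TOL:
            k = kk
        fixed[j] = int(k[j])
    return k


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle
# ---------------------------------------------------------------------------


def brute_force(problem: ProblemSpec, guard: int = BRUTE_FORCE_GUARD) -> DietSolution:
    """Exhaustively enumerate every integer serving vector; same contract
    as :func:`optimize` including the lexicographic tie-break.

    Enumeration order is lexicographic in database item order (last item
    varies fastest), and a candidate replaces the incumbent only when its
    cost is smaller by more than the 1e-9 cost tolerance — so the first
    optimum found is the lexicographically smallest.

    Raises
    ------
    ValueError
        If the search space exceeds ``guard`` vectors (with the size
        estimate in the message).
    """
    rows, lb, ub, cost, cap_units, _ = _assemble(problem)
    sizes = (cap_units.astype(int) + 1).tolist()
    space = math.prod(sizes)
    if space > guard:
        raise ValueError(
            f"brute-force search space {space} exceeds guard {guard}"
        )

    n = len(sizes)
    best_cost = math.inf
    best_k: np.ndarray | None = None

    # chunked lexicographic enumeration: decode linear index -> mixed radix
    radix = np.ones(n, dtype=np.int64)
    for j in range(n - 2, -1, -1):
        radix[j] = radix[j + 1] * sizes[j + 1]

    for start in range(0, space, _ENUM_CHUNK):
        idx = np.arange(start, min(start + _ENUM_CHUNK, space), dtype=np.int64)
        K = (idx[:, None] // radix[None, :]) % np.array(sizes, dtype=np.int64)[None, :]
        vals = K @ rows.T  # (chunk, n_constraints)
        feas = np.all(vals >= lb[None, :] - SERVING_TOL, axis=1) & np.all(
            vals <= ub[None, :] + SERVING_TOL, axis=1
        )
        if not feas.any():
            continue
        costs = K[feas] @ cost
        order = np.argmin(costs)
        if costs[order] < best_cost - COST_TOL:
            # ties within the chunk: argmin returns the first (lex smallest)
            within = np.flatnonzero(costs <= costs[order] + COST_TOL)
            best_cost = float(costs[within[0]])
            best_k = K[feas][within[0]].astype(int)

    if best_k is None:
        return DietSolution(status="infeasible")
    return _build_solution(problem, best_k)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def binding_report(
    solution: DietSolution, problem: ProblemSpec, tol_fraction: float = 0.05
) -> BindingReport:
    """Classify each nutrient and group constraint as at-lower, at-upper or
    interior at the optimum.

    A value counts as binding when it lies within ``tol_fraction`` of the
    bound span (or of the lower bound itself when unbounded above) — the
    tolerance acknowledges that integer portions land *near* a bound rather
    than exactly on it (e.g. potassium 4703.5 against a 4700 floor).
    """
    if not solution.is_optimal:
        raise ValueError("binding_report requires an optimal solution")
    report = BindingReport()
    entries: list[tuple[str, str, float, float, float | None]] = []
    for code in NUTRIENTS:
        b = problem.nutrient_constraints[code]
        entries.append((code, "nutrient", solution.achieved[code], b.lower, b.upper))
    for cat in ALL_CATEGORIES:
        b = problem.group_constraints[cat]
        entries.append(
            (cat.value, "group", solution.group_servings.get(cat, 0.0), b.lower, b.upper)
        )
    for name, kind, value, lower, upper in entries:
        if upper is not None:
            tol = tol_fraction * (upper - lower)
            slack_upper = upper - value
        else:
            tol = tol_fraction * lower
            slack_upper = math.inf
        slack_lower = value - lower
        near_lower = slack_lower <= tol
        near_upper = slack_upper <= tol
        if near_lower and near_upper:
            side = "lower" if slack_lower <= slack_upper else "upper"
        elif near_lower:
            side = "lower"
        elif near_upper:
            side = "upper"
        else:
            side = "none"
        relpos = None
        if upper is not None and upper > lower:
            relpos = (value - lower) / (upper - lower)
        report[name] = ConstraintStatus(
            name=name,
            kind=kind,
            value=value,
            lower=lower,
            upper=upper,
            side=side,
            slack_lower=slack_lower,
            slack_upper=slack_upper,
            relative_position=relpos,
        )
    return report


def _relaxation_candidates(problem: ProblemSpec):
    from dataclasses import replace as _replace

    from .constraints import Bound

    for code in NUTRIENTS:
        b = problem.nutrient_constraints[code]
        if b.lower > 0:
            nc = problem.nutrient_constraints.replace(**{code: Bound(0.0, b.upper)})
            yield f"{code}:lower", _replace(problem, nutrient_constraints=nc)
        if b.upper is not None:
            nc = problem.nutrient_constraints.replace(**{code: Bound(b.lower, None)})
            yield f"{code}:upper", _replace(problem, nutrient_constraints=nc)
    for cat in ALL_CATEGORIES:
        b = problem.group_constraints[cat]
        if b.lower > 0:
            gc = problem.group_constraints.replace({cat: Bound(0.0, b.upper)})
            yield f"{cat.value}:lower", _replace(problem, group_constraints=gc)
        if b.upper is not None:
            gc = problem.group_constraints.replace({cat: Bound(b.lower, None)})
            yield f"{cat.value}:upper", _replace(problem, group_constraints=gc)


def diagnose_infeasibility(problem: ProblemSpec) -> InfeasibilityDiagnosis:
    """Find single constraints whose removal restores feasibility.

    Each nutrient/group lower bound is dropped to 0 and each finite upper
    bound lifted to unbounded, one at a time, re-solving after each
    relaxation.  Transparent one-constraint-at-a-time probing, not an
    irreducible-infeasible-subsystem computation: when two independent
    impossibilities coexist, no single culprit exists and ``irreducible``
    is set.

    Raises
    ------
    ValueError
        If the problem is actually feasible.
    """
    if optimize(problem, refine_ties=False).is_optimal:
        raise ValueError("diagnose_infeasibility called on a feasible problem")
    culprits = []
    for name, relaxed in _relaxation_candidates(problem):
        if optimize(relaxed, refine_ties=False).is_optimal:
            culprits.append(name)
    return InfeasibilityDiagnosis(
        culprit_constraints=culprits, irreducible=not culprits
    )


# ---------------------------------------------------------------------------
# Scenario comparison
# ---------------------------------------------------------------------------


def compare_scenarios(
    db: FoodDatabase,
    trimester: int,
    scenarios: Sequence[SupplementScenario],
    overrides=None,
    refine_ties: bool = False,
) -> pd.DataFrame:
    """Minimal diet cost with and without each supplement scenario.

    Returns one row per scenario plus a leading baseline (no-supplement)
    row: scenario name, status, cost, binding lower-bound summary and the
    achieved amounts for every tracked nutrient.  A failure in one row is
    recorded there (status ``error``) without aborting the rest.
    """
    base = build_problem(db, trimester, overrides)
    rows = []
    runs: list[tuple[str, ProblemSpec | None, str | None]] = [("baseline", base, None)]
    for sc in scenarios:
        try:
            runs.append((sc.name, base.with_supplement(sc), None))
        except Exception as exc:  # malformed scenario: record, keep going
            runs.append((sc.name, None, str(exc)))

    for name, prob, err in runs:
        rec: dict = {"scenario": name}
        if prob is None:
            rec.update(status="error", total_cost=math.nan, error=err)
            rows.append(rec)
            continue
        try:
            sol = optimize(prob, refine_ties=refine_ties)
        except Exception as exc:
            rec.update(status="error", total_cost=math.nan, error=str(exc))
            rows.append(rec)
            continue
        rec["status"] = sol.status
        rec["total_cost"] = sol.total_cost
        rec["error"] = None
        if sol.is_optimal:
            rep = binding_report(sol, prob)
            rec["binding_lower"] = ",".join(rep.at_lower())
            rec["binding_upper"] = ",".join(rep.at_upper())
            for code in NUTRIENTS:
                rec[f"achieved_{code}"] = sol.achieved[code]
        rows.append(rec)
    return pd.DataFrame(rows)


def check_solution(solution: DietSolution, problem: ProblemSpec) -> bool:
    """Independent feasibility re-check of an optimal solution.

    Re-derives nutrient totals and cost through :func:`evaluate_servings`
    and verifies every nutrient bound, group bound, item cap and the
    granularity of each serving, all at the serving tolerance.
    """
    if not solution.is_optimal:
        raise ValueError("check_solution requires an optimal solution")
    achieved, cost = evaluate_servings(solution.servings, problem.db)
    if not achieved.allclose(solution.achieved):
        return False
    if abs(cost - solution.total_cost) > 1e-9 + 1e-12 * abs(cost):
        return False
    for code in NUTRIENTS:
        if not problem.nutrient_constraints[code].contains(achieved[code]):
            return False
    cat_totals = {c: 0.0 for c in ALL_CATEGORIES}
    for item_id, s in solution.servings.items():
        item = problem.db[item_id]
        if s < -SERVING_TOL or s > problem.item_caps.cap_for(item) + SERVING_TOL:
            return False
        units = s / problem.granularity
        if abs(units - round(units)) > SERVING_TOL:
            return False
        cat_totals[item.category] += s
    for cat in ALL_CATEGORIES:
        if not problem.group_constraints[cat].contains(cat_totals[cat]):
            return False
    return True
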