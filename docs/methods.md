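# Methods

## The model

`dietopt` solves the classical least-cost diet problem with integer
portions.  For food items j = 1..n with per-serving price c_j and
per-serving nutrient content a_ij (nutrient i), it finds servings x_j
minimizing

    p = Σ_j c_j x_j

subject to

    l_i  ≤ Σ_j a_ij x_j ≤ u_i        for each tracked nutrient i,
    L_g  ≤ Σ_{j∈g} x_j  ≤ U_g        for each food category g,
    0    ≤ x_j ≤ cap_j               per-item repetition caps,
    x_j  = k_j · γ,  k_j ∈ ℤ≥0       integer multiples of the granularity γ.

The nutrient bounds are the Malaysian RNI 2017 recommendations for
pregnant women, per trimester; the category bounds are the MDG 2010
food-group serving recommendations for the seven food groups (cereals
and grains, fruits, vegetables, meat/poultry, fish, legumes, milk and
dairy products) plus palatability bounds of 1–4 servings on sugar, salt
and oil.  Palatability constraints keep the cost minimizer from returning
degenerate menus (e.g. unbounded sugar as cheap energy); the per-item
caps (default 2 servings/day, fish 1 serving/day) limit repetition of a
single dish through the day.

### Integer portions at half-serving granularity

The program requires integer portions, yet the food-group
recommendations themselves contain half servings (meat and legumes have
0.5-serving floors).  Both are reconciled by making the decision
variables integer counts of γ = 0.5 serving.  γ is configurable; caps
must be multiples of γ.

### Tracked nutrient panel

Fifteen quantities: energy (kcal), protein, carbohydrate, fat, fibre
(g), vitamin A (RE), vitamins C, B1, B2, B3, sodium, potassium, calcium,
iron, phosphorus (mg).  The panel is closed — folic acid, vitamin D and
fatty acids are deliberately excluded, mirroring the coverage limits of
the food-composition data the model is designed around.  A folic-acid
supplement therefore has no effect on the tracked constraints.

### Supplement scenarios

A supplement scenario is a vector of exogenous daily nutrient amounts
(the packaged trimester-2/3 regimen: 100 mg elemental iron — the RNI
2017 supplementation figure — plus vitamin C 100 mg and a B-complex of
B1 5 mg / B2 5 mg / B3 20 mg; the C and B-complex compositions are
package defaults, not published regimens, and fully configurable).
Supplements relax *lower* bounds only: new_lower = max(0, lower −
provided).  Dietary upper bounds are untouched — they constrain food
intake, and a 100 mg iron regimen intentionally exceeds the 29 mg
dietary iron ceiling; counting supplements against dietary ceilings
would make every iron-supplemented program infeasible by construction.
Supplement cost is not modelled (the packaged regimen is the free
public-sector one).

## Solving and determinism

The integer program is solved by branch-and-bound over the continuous
relaxation (HiGHS, via `scipy.optimize.milp`) with a zero MIP gap, so
returned optima are global.  Tolerances: integer feasibility 1e-6
serving units; cost comparisons 1e-9 currency units.

Cost ties are real (many items share prices), so the optimizer
deterministically returns the lexicographically smallest serving vector
in database order among all solutions within 1e-9 of the optimal cost.
This is implemented as sequential variable minimization under a cost-cap
constraint — one extra MILP per item.  Callers that need only status and
cost (scenario sweeps, infeasibility probing) disable the refinement via
`refine_ties=False`.

`brute_force` re-implements the identical contract by chunked exhaustive
enumeration in lexicographic order (guarded at 10^7 candidate vectors) and
serves as the independent oracle: on 200 random small instances per run,
status, optimal cost and tie-broken serving vectors must agree exactly.
The feasibility of every optimum is additionally re-checked through
`evaluate_servings`, an accounting path independent of the solver's
constraint matrix.

### Binding constraints and infeasibility diagnosis

A constraint is reported binding when the achieved value lies within
`tol_fraction` (default 5%) of the bound span — or of the lower bound
itself when unbounded above.  The tolerance is deliberate: integer
portions land *near* bounds (e.g. potassium 4703.5 mg against a 4700 mg
floor), and exact-equality classification would miss precisely the
constraints that drive the solution.

`diagnose_infeasibility` relaxes one constraint at a time (lower bound
to 0, upper bound to +∞) and re-solves.  This transparent
single-relaxation probe matches how a nutritionist reasons ("the iron
floor alone is unattainable"); it is *not* an irreducible-infeasible-
subsystem computation, and when two independent impossibilities coexist
it reports `irreducible=True` with no culprits.

## Adequacy statistics

Per-subject mean daily intakes are equal-weight averages over recorded
days (a 24-h recall plus a multi-day food record are treated alike).
"Achieving the RNI" means mean intake ≥ the RNI lower bound, inclusive,
with a configurable threshold fraction (default 1.0).  Macronutrient
energy shares use Atwater factors 4/4/9 kcal/g for
carbohydrate/protein/fat — the convention of Malaysian food-composition
practice.  Printed-range category conventions: "10–10.9 g/dL" is the
half-open interval [10.0, 11.0), so the haemoglobin classes (moderate
anaemia [8, 10), mild [10, 11), normal [11, 16]) tile the observed
range, and anaemia is Hb < 11 g/dL; BMI uses the Asian cut-points
(<18.5, [18.5, 23), [23, 27.5), [27.5, 35)).  Values outside all printed
ranges get an explicit `out_of_range` category, never silent clamping.
Reported percentages are rounded half-up to one decimal, matching
survey-table convention; standard deviations are sample SDs (n−1), and a
single-subject cohort reports SD as not available.

## The synthetic-data generator

No national food-composition database or market-price survey is
redistributable, so all validation runs on synthetic stand-ins.

* **Food databases** — per-serving nutrient densities are log-normal
  around category-specific medians (σ = 0.35 log-units), chosen from
  standard food-composition knowledge for the serving definitions in
  use: one cereal serving = 30 g carbohydrate (≈140 kcal), one meat or
  fish serving = 14 g protein, one legume or milk serving = 7 g protein,
  one oil serving = 9 g fat, one sugar serving = 5 g carbohydrate, one
  salt serving ≈ 1 g NaCl = 390 mg sodium (the serving-size convention
  tables define servings for the other palatability items but not salt,
  so the 1 g figure is a package default).  Prices are log-normal
  (σ = 0.30) around category medians in an abstract currency.  The
  default database has 200 items across all 10 categories.  These
  defaults are calibrated so that the full trimester-2 program is
  feasible in ≥90% of seeds (measured 50/50 on the default size and
  30/30 on the reduced sweep size) — an intentionally realistic regime
  in which iron, calcium and potassium emerge as the typical binding
  floors.
* **Dietary records** — subjects draw 8–14 items/day with Dirichlet
  personal-preference weights.  A requested RNI-exceedance fraction for
  a nutrient is hit exactly in distribution: each subject is an achiever
  with that probability, and the subject's servings are rescaled to land
  above or below the cut-off by a log-normal margin.  With several
  simultaneous targets only the first is matched exactly; achieved
  fractions for the rest are reported in a warning when off by more than
  5 points.  Covariates are drawn from the packaged cohort mixture
  (haemoglobin classes 55/17/6 per 78, log-normal BMI with mean 24.3 and
  SD 4.7 kg/m², gravidity frequencies 17/19/20/10/7/4/1, trimester
  weights 0.25/0.52/0.23, 85.9% supplement use).
* **Known-optimum instances** — two constructions, because pinned
  geometry alone is degenerate: (a) *pinned*: caps are set exactly to a
  drawn serving vector s\* and each group floor to the group's total, so
  caps force x ≤ s\* componentwise while the group sums force equality —
  s\* is the unique feasible point by construction; (b) *oracle*: small
  random instances solved by exhaustive enumeration.
* **Iron scarcity** — `make_iron_scarce` scales every item's iron by a
  factor; choosing the factor so the cap-weighted total attainable iron
  falls below the 20 mg floor yields a certifiably infeasible program
  whose diagnosis must name the iron floor.

What the generator does **not** emulate: nutrient–nutrient correlations
within foods (each density is drawn independently), recipe structure and
shared ingredients, seasonal and regional price variation, intra-subject
day-to-day menu correlation, and under-reporting.  Green tests therefore
certify the machinery — exact optimization, correct accounting, correct
constraint encoding — on *plausible* inputs, not the nutritional
conclusions for any real food supply.

## Problem sizes

The validation suites use database/instance sizes chosen to exercise the
machinery densely: ≤8-item instances with caps of four half-serving
units for enumeration cross-checks (200 instances), ~80-item databases
for the 100-instance supplement sweep and the 20-seed scarcity
diagnosis, the 200-item default for single end-to-end solves, and 500
simulated subjects for adequacy calibration.

## Known limitations

* Single-day optimization only: no multi-day joint planning, no goal
  programming or weighted-deviation variants.
* No bioavailability modelling (phytate inhibition, ascorbate
  enhancement of non-haem iron absorption are outside the linear
  model).
* Currency is abstract; no exchange-rate handling.
* The menu assembler is deterministic cosmetic slotting (staples to main
  meals, fruits/milk/sugar to tea breaks first, max one appearance of an
  item per slot); it conserves the serving vector exactly but makes no
  claim of culinary coherence.
* The lexicographic refinement costs n extra MILP solves; on large
  databases with ties it dominates run time, which is why sweep code
  paths disable it.
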