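# dietopt

Least-cost diet optimization for pregnancy nutrition.

`dietopt` answers a practical public-health question: **what is the
cheapest daily combination of locally available foods that meets all
nutrient recommendations for a pregnant woman — and which nutrients make
that diet expensive or impossible?**  It is written for nutrition
researchers and dietitians who design food-based recommendations from a
food-composition table and local prices, and who need the optimization,
the diagnostics and the cohort dietary-assessment statistics in one
reproducible package.

## The model

For foods *j* with per-serving price *c<sub>j</sub>* and nutrient
content *a<sub>ij</sub>*, the package solves the integer least-cost diet
program

> min p = Σ<sub>j</sub> c<sub>j</sub> x<sub>j</sub>
> subject to  l<sub>i</sub> ≤ Σ<sub>j</sub> a<sub>ij</sub> x<sub>j</sub> ≤ u<sub>i</sub>,
> L<sub>g</sub> ≤ Σ<sub>j∈g</sub> x<sub>j</sub> ≤ U<sub>g</sub>,
> 0 ≤ x<sub>j</sub> ≤ cap<sub>j</sub>,  x<sub>j</sub> ∈ ½·ℤ

with nutrient bounds l, u from the Malaysian **RNI 2017** (15 tracked
nutrients, per pregnancy trimester), food-group serving bounds L, U from
the **MDG 2010** food pyramid (seven food groups) plus palatability
bounds on sugar, salt and oil, and per-item caps limiting repetition of
any single dish.  Portions are integer half-servings.  Solutions are
globally optimal (branch-and-bound, zero MIP gap) and deterministic
(lexicographic tie-break in database order).

On top of the optimizer the package provides:

* **supplement scenarios** — exogenous nutrient amounts (e.g. 100 mg/day
  elemental iron) relax dietary lower bounds; compare menu costs with
  and without supplementation,
* **binding-constraint reports** — which recommendations pin the optimum
  (iron, calcium and potassium floors, typically),
* **infeasibility diagnosis** — which single bound, relaxed, restores
  feasibility,
* **menu assembly** — deterministic arrangement of the serving vector
  over five meal slots,
* **adequacy statistics** — per-subject mean intakes from dietary
  recall/record data, percent of a cohort achieving each RNI,
  macronutrient energy shares (Atwater 4/4/9), haemoglobin/BMI/gravidity
  summaries,
* **synthetic generators** — seeded food databases, dietary records and
  optimization instances with known ground truth, since national
  food-composition tables are not redistributable.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```python
import dietopt as d

db = d.generate_food_db(d.GeneratorParams(seed=1))   # 200 synthetic foods
problem = d.build_problem(db, trimester=2)           # RNI 2017 + MDG 2010
solution = d.optimize(problem)
print(f"status: {solution.status}")
print(f"minimal daily food cost: {solution.total_cost:.2f}")
print(f"items selected: {len(solution.servings)}")
report = d.binding_report(solution, problem)
print("nutrients at their RNI floor:",
      [n for n in report.at_lower() if report[n].kind == "nutrient"])

iron = d.default_supplement_scenario(2)              # 100 mg iron + C + B-complex
table = d.compare_scenarios(db, 2, [iron])
print(table[["scenario", "status", "total_cost"]].to_string(index=False))
```

prints

```
status: optimal
minimal daily food cost: 6.91
items selected: 15
nutrients at their RNI floor: ['energy_kcal', 'carb_g', 'vitB2_mg', 'sodium_mg', 'potassium_mg', 'calcium_mg', 'iron_mg']
                                 scenario  status  total_cost
                                 baseline optimal     6.91255
folic acid + iron + B complex + vitamin C optimal     6.57255
```

Reading the numbers: the cheapest trimester-2 diet from this synthetic
food supply costs 6.91 currency units/day and is pinned at the lower
recommended amounts of iron, calcium and potassium among others — these
floors force expensive foods into the basket.  Providing the free
antenatal supplement regimen relaxes the iron and B-vitamin floors and
the minimal food cost drops to 6.57 (supplementation can never raise
it).  Costs are in the abstract currency of the synthetic price
generator.

The same pipeline is scriptable from a shell:

```sh
dietopt synth --seed 1 --out data/
dietopt validate  --db data/food_db.csv
dietopt optimize  --db data/food_db.csv --trimester 2 --out run/
dietopt scenarios --db data/food_db.csv --trimester 2 --out run/
dietopt adequacy  --db data/food_db.csv --records data/records.csv \
                  --covariates data/covariates.csv --out run/
```

An infeasible diet is a *finding*, not an error: `optimize` exits 0 with
`"status": "infeasible"` recorded in `solution.json`.

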