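# Methods

`neutroplan` plans the resources of a healthcare facility — staff
headcounts, medical-device counts, drug stocks, and the budgets that fund
them — over a multi-decade horizon, under imprecise budget information.
This note records the model, its assumptions, the numerical choices, and
the limits of what the tests demonstrate.

## Demand model

Patient demand is a linear trend. An ordinary-least-squares line fitted to
annual patient totals gives `XP(t) = intercept + slope * t` (patients per
year, `t` in years since the base period). The bundled oncology-center
scenario fits `XP = 1227 + 3526 t` from its three annual totals
(1809, 3589, 8861) and pins the per-working-day form at
`XP_day = 5 + 10 t` as the case study's own convention; users fitting their
own data can derive a daily form with an explicit working-days divisor
(default 250) instead. There is no seasonality and no forecast uncertainty:
the trend is treated as exact when projecting targets.

Targets grow **linearly, not compounded**:

* budgets: `B(t) = B * (1 + GR * t)` with annual growth rate `GR`
  (0.08 for the bundled scenario);
* drug demand: `QD_k(t) = ceil(QD_k * (1 + GR * t))`;
* staff: `TNS_i(t) = ceil(SH * XP_day(t) / XR_i)` where `XR_i` is the
  patients-per-staff service ratio and `SH` the number of shifts (2 in the
  bundled scenario — a value that reproduces the case study's staffing
  plans for every projected year);
* devices: `TNM_j(t) = ceil(XP_day(t) / YR_j)`. Devices are shared across
  shifts by default because the shift-free form reproduces five of the
  seven published device counts while the shift-multiplied form reproduces
  one; a flag restores the multiplier. The two remaining device types
  (blood-test and miscellaneous small equipment) match neither form and
  are deliberately out of scope.

Integer targets are ceilings of their real-valued formulas, evaluated in
exact rational arithmetic with a 1e-9 relative snap to the nearest
integer. This matters: in floating point, `275 * (1 + 0.08*28)` lands a
hair above 891 and would ceil to 892, corrupting a target by one unit.

## Neutrosophic budgets

Each budget may be a generalized triangular neutrosophic number (GTNN): a
mean `a` with triangular truth, indeterminacy and falsity profiles, peak
truth degree `w`, valley degrees `u` and `y`, and six spreads. The degrees
satisfy `0 <= w, u, y <= 1` and `w + u + y <= 3`; `w > 0` is required
because the truth cut divides by it. The truth branches are scaled by `w`
so that membership evaluation and the alpha-cut are mutually inverse.
Zero spreads degenerate gracefully to a crisp point; only a cut that would
divide by zero (valley degree 1 below level 1) raises.

Cutting the three profiles at levels `(alpha, beta, gamma)` gives three
intervals with midpoints

```
m_alpha = a + (r_mu - l_mu)/2 * (1 - alpha/w)
m_beta  = a + (r_sigma - l_sigma)/2 * (beta - u)/(1 - u)
m_gamma = a + (r_nu - l_nu)/2 * (gamma - y)/(1 - y)
```

Deneutrosophication is either the **average** of the three midpoints (the
single-valued route) or a **choice among them** left to the optimizer (the
multi-choice route). The bundled scenario evaluates all budgets at
`(0.1, 0.9, 0.8)`. Two recorded infidelities of the source material: the
published gamma-column of the midpoint table does not satisfy its own
stated formula for any budget (we implement the formula literally), and
the total budget's falsity spreads produce a support crossing zero
(stored as published; the validator warns). The minimum-of-cuts set is
exposed as a derived utility only; no model consumes it.

## Goal-programming models

For each period, integer variables `x_i, y_j, z_k` count staff, devices
and drugs. Each resource carries a goal `var + n - p = raw_target` with
nonnegative deviations, *and* a hard floor `var >= raw_target` (care
cannot be rationed below the requirement). With integrality, the floor
makes the ceiling the optimum, and the residue (e.g. 143 - 142.5 = 0.5)
appears as a positive deviation — exactly the fractional deviations the
case study reports.

The four budget goals (total, staff, devices, drugs) compare the realized
spend with the period's budget aspiration. They default to the one-sided
form `spend + n - p <= aspiration`: only overspend (`p`) is binding at
optimality; a budget left under-used is slack, not a failure. This is a
deliberate design choice over the soft-equality reading: with equalities
and both deviations penalized, any under-budget period makes the optimizer
inflate cheap resources (hundreds of thousands of surplus tablets in the
base year) purely to fill the budget — contradicting the projected plans
the formulation is meant to produce. An `equality` mode is provided for
completeness and behaves exactly that way. Objective weights default to 1
per goal (nonpreemptive); preemptive priorities are not implemented.

Variants:

* **GP** — budget aspirations are the crisp budgets grown per period.
* **NGP** — aspirations are the crisp values of the budget GTNNs, computed
  once from the base GTNN and then grown per period (growing the spreads
  proportionally instead yields the same crisp value, so the order is
  benign).
* **NMCGP** — each budget goal carries the three cut midpoints as
  candidate aspirations with three exclusive selection binaries summing
  to 1. This is an exact linearization of the published two-binary product
  encoding with the all-zero pair excluded. Under the one-sided budget
  relation the optimizer prefers the largest candidate; under `equality`
  it picks the closest.

**Device-budget transfer.** An optional block adds an indicator binary per
device (`delta_j = 1` iff the count strictly exceeds its target, enforced
by big-M pairs; big-M defaults to 10x the largest aspiration and must
exceed every reachable value). `aggregate` mode (the narrative reading)
raises the staff-budget aspiration by the unit cost of every device left
at target. `literal` mode adds the published per-device spending bands,
which pin the staff spend to two different constants simultaneously and
are jointly infeasible for heterogeneous device costs — kept verbatim so
the infeasibility is demonstrable rather than silently repaired. Neither
mode claims to reproduce the published budget-deviation rows, whose
bookkeeping is internally inconsistent (their staff- and drug-deviation
rows are identical for all years).

## Solving and determinism

Models are stored as a solver-agnostic structure (integer count variables,
goal constraints with deviation pairs, hard constraints, binaries) and
flattened to `scipy.optimize.milp` (HiGHS branch-and-cut, single thread,
zero relative gap). An LP-format text export is available for debugging.
Deviations, realized aspirations and the objective are recomputed from the
rounded integer solution in exact closed form (`n = max(g - f, 0)`,
`p = max(f - g, 0)` for equalities; one-sided goals pay only the violated
side), so repeated runs write byte-identical reports. Complementarity
`n * p = 0` is never imposed — it holds at optimality because both
deviations carry positive weight — and is asserted post-solve.

The brute-force oracle enumerates all integer assignments of tiny models
(selection binaries one-hot per goal, enumeration capped at 1e6) and
shares the deviation closed form with the solver read-back; solver-vs-
oracle agreement therefore tests the MILP construction itself.

## Synthetic scenarios

The generator emulates the structure of the bundled case: catalog sizes
8/7/40 by default, unit costs and service ratios spanning the published
catalogs (staff cost 2400–9600, device cost 200–9600, drug price
0.1–420, ratios 3–100), base budgets equal to base-catalog cost times a
slack factor (1.0–1.3), GTNN budgets built around those crisp means with
spreads 2–30% of the mean and degrees drawn to respect `w + u + y <= 3`,
8% growth, two shifts. It does not emulate demand seasonality, catalog
churn, price inflation, or correlated budget shocks — passing tests say
the optimization machinery is correct under the stated structure, not
that the linear-growth demand model fits any particular facility.

## Problem sizes used in tests

The full bundled scenario (55 integer count variables, 59 goals, nine
periods) solves in well under a second per period. Oracle-equivalence
property tests use scenarios with 2 staff / 1 device / 2 drugs, counts
enumerated up to two units above their floors, across 50 seeds and all
three variants; the multi-choice cross-check enumerates all 3^4 aspiration
combinations of a tiny model against the integrated MILP.

## Known limitations

* Only the final-year staffing/drug plan and the per-period closed-form
  tables are reproduced against the published case study; the published
  solution tables for the neutrosophic variants reflect solver-dependent
  alternate optima (their base-year staffing exceeds every stated
  requirement) and are not an acceptance surface.
* Growth reporting uses explicit CAGR and mean period-over-period growth;
  the growth percentages printed in the source tables follow no formula
  we could derive and are not matched.
* Currency is unit-less; no exchange rates, inflation, or multi-site
  scenarios. Monthly patient counts are kept only as annual totals.
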