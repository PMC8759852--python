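# neutroplan

Goal-programming models for long-horizon healthcare resource planning
under imprecise budgets, with neutrosophic (truth / indeterminacy /
falsity) budget modeling.

A planner at a healthcare facility — the bundled case is an oncology
center planning 2018–2048 — must decide, for every future period, how many
staff of each kind to employ, how many medical devices to operate, and how
many units of each drug to stock, while tracking four budgets (total,
staff, devices, drugs) that are themselves uncertain. `neutroplan` targets
operations-research practitioners and health-system planners who want
those plans as reproducible optimization output rather than spreadsheet
arithmetic.

## The models

Patient demand follows a fitted linear trend; per-period targets are

```
TNS_i(t) = ceil(SH · XP_day(t) / XR_i)      staff of kind i
TNM_j(t) = ceil(XP_day(t) / YR_j)           devices of type j
QD_k(t)  = ceil(QD_k · (1 + GR·t))          drug k demand
B(t)     = B · (1 + GR·t)                   each budget
```

with `XP_day(t)` the daily patient load, `XR_i`/`YR_j` service ratios,
`GR` the annual patient growth rate and `SH` the number of shifts. A
mixed-integer goal program minimizes the weighted deviations

```
min  Σ_l W_l (n_l + p_l) + Σ_i (nx_i + px_i) + Σ_j (ny_j + py_j) + Σ_k (nz_k + pz_k)
s.t. spend_l + n_l − p_l ≤ B_l(t)           budget goals
     v + n_v − p_v = target_v,  v ≥ target_v  per resource count v
     all counts integer, deviations ≥ 0
```

Each budget `B_l` can be a **generalized triangular neutrosophic number**
(GTNN) `⟨(a, l_μ, r_μ; w), (a, l_σ, r_σ; u), (a, l_ν, r_ν; y)⟩`. Cutting
its three membership profiles at levels `(α, β, γ)` yields three intervals;
their midpoints deneutrosophize the budget either as their average (the
**NGP** variant) or as a three-way choice the optimizer makes through
exclusive selection binaries (the **NMCGP** variant). The crisp **GP**
variant uses the budget means directly. An optional indicator-constraint
block transfers unspent device budget to the staff budget.

## Worked example

```python
import neutroplan as nt

scenario = nt.builtin_alamal()          # the bundled oncology-center case
report = nt.plan_horizon(scenario, "gp")

final = report.staff_table.query("year == 2048")
print(final[["staff", "count", "cost"]].to_string(index=False))
print("staff total:", final["count"].sum(),
      " drug units:", report.drug_table.query("year == 2048").quantity.sum())
```

prints

```
            staff  count   cost
      oncologists     38 364800
  general doctors     29 111360
     radiologists     57 328320
      pharmacists      6  20160
  lab technicians     57 191520
x-ray technicians     19  59280
           nurses    143 343200
      other staff     57 205200
staff total: 406  drug units: 143223
```

i.e. by 2048 (t = 28, 285 patients/day) the center needs 406 staff —
38 oncologists and 143 nurses among them — at an annual staff cost of
$1,623,840, and 143,223 drug units costing $658,539.2. The same call with
`"ngp"` or `"nmcgp"` substitutes deneutrosophied budget aspirations, and
`nt.compare_variants([...])` tabulates the three variants side by side.

The same runs from the shell:

```
neutroplan plan --scenario alamal --model nmcgp --alpha 0.1 --beta 0.9 \
    --gamma 0.8 --out plan_out
neutroplan compare --out cmp_out
```

Scenarios load from a single JSON document or a CSV bundle
(`staff.csv`, `devices.csv`, `drugs.csv`, `periods.csv`, `budgets.json`);
see `neutroplan validate --help`.

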