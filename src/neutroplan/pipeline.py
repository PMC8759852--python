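"""Solve planning models over a horizon and assemble report tables.

The MILPs are solved with the HiGHS branch-and-cut engine behind
:func:`scipy.optimize.milp` (single-threaded and deterministic, solved to
zero relative gap).  Deviations and the objective are recomputed from the
integer solution in exact closed form, so two runs with the same options
produce byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .goals import (
    BUDGET_LABELS,
    GoalModel,
    ModelError,
    Solution,
    build_gp,
    build_ngp,
    build_nmcgp,
    check_complementarity,
    device_transfer_constraints,
    evaluate_assignment,
)
from .gtnn import CutLevels
from .scenario import Scenario
from .targets import (
    DEFAULT_DAILY_BASE,
    DEFAULT_DAILY_SLOPE,
    targets_for_period,
)

__all__ = [
    "SolverOptions",
    "PlanReport",
    "PlanningError",
    "solve_model",
    "plan_horizon",
    "growth_summary",
    "compare_variants",
    "write_report",
    "DEFAULT_CUT_LEVELS",
]

logger = logging.getLogger("neutroplan")

# The case study evaluates every neutrosophic budget at these levels.
DEFAULT_CUT_LEVELS = CutLevels(alpha=0.1, beta=0.9, gamma=0.8)

_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded",
           4: "error"}


class PlanningError(RuntimeError):
    """A period could not be solved to optimality."""


@dataclass(frozen=True)
class SolverOptions:
    """Deterministic solve settings.

    ``seed`` is accepted for interface stability; the HiGHS run is
    single-threaded and deterministic, so it does not influence results.
    """

    seed: int = 0
    mip_rel_gap: float = 0.0
    time_limit: float | None = None
    complementarity_tol: float = 1e-6


def _model_matrices(m: GoalModel):
    """Flatten a GoalModel into scipy.optimize.milp inputs."""
    names = [v.name for v in m.all_vars()]
    var_objs = list(m.all_vars())
    for g in m.goals:
        names.extend([g.neg_dev, g.pos_dev])
    index = {n: i for i, n in enumerate(names)}
    nvar = len(names)

    c = np.zeros(nvar)
    integrality = np.zeros(nvar)
    lb = np.zeros(nvar)
    ub = np.full(nvar, np.inf)
    for i, v in enumerate(var_objs):
        integrality[i] = 1
        lb[i] = v.lb
        if v.ub is not None:
            ub[i] = v.ub
    for g in m.goals:
        c[index[g.neg_dev]] = g.weight
        c[index[g.pos_dev]] = g.weight

    rows, cols, vals, clb, cub = [], [], [], [], []

    def add_row(coeffs: dict, lo, hi):
        r = len(clb)
        for name, coef in coeffs.items():
            rows.append(r)
            cols.append(index[name])
            vals.append(float(coef))
        clb.append(-np.inf if lo is None else float(lo))
        cub.append(np.inf if hi is None else float(hi))

    for g in m.goals:
        coeffs = dict(g.expression)
        coeffs[g.neg_dev] = coeffs.get(g.neg_dev, 0.0) + 1.0
        coeffs[g.pos_dev] = coeffs.get(g.pos_dev, 0.0) - 1.0
        if g.choices is not None:
            for cv, sv in zip(g.choices, g.choice_vars):
                coeffs[sv] = coeffs.get(sv, 0.0) - cv
        if g.relation == "eq":
            add_row(coeffs, g.aspiration, g.aspiration)
        elif g.relation == "le":
            add_row(coeffs, None, g.aspiration)
        else:
            add_row(coeffs, g.aspiration, None)
    for h in m.hard:
        add_row(h.expression, h.lb, h.ub)

    A = sparse.csc_array((vals, (rows, cols)), shape=(len(clb), nvar))
    constraints = optimize.LinearConstraint(A, np.array(clb), np.array(cub))
    bounds = optimize.Bounds(lb, ub)
    return names, c, integrality, bounds, constraints


def solve_model(m: GoalModel, opts: SolverOptions | None = None) -> Solution:
    """Solve a GoalModel to proven optimality.

    Infeasible or unbounded models are surfaced in ``Solution.status``.
    Deviations, realized aspirations and the objective are recomputed from
    the rounded integer assignment; the complementarity check runs
    automatically (it holds at optimality because both deviations of every
    goal carry positive weight).
    """
    opts = opts or SolverOptions()
    names, c, integrality, bounds, constraints = _model_matrices(m)
    milp_options = {"mip_rel_gap": opts.mip_rel_gap, "presolve": True}
    if opts.time_limit is not None:
        milp_options["time_limit"] = opts.time_limit
    res = optimize.milp(c=c, constraints=constraints, bounds=bounds,
                        integrality=integrality, options=milp_options)
    status = _STATUS.get(res.status, "error")
    if status != "optimal":
        logger.warning("solver finished with status %s: %s", status,
                       res.message)
        return Solution(status=status)

    values = dict(zip(names, res.x))
    assignment = {v.name: int(round(values[v.name])) for v in m.all_vars()}
    evaluated = evaluate_assignment(m, assignment)
    if evaluated is None:
        raise ModelError("solver returned an assignment violating a hard "
                         "constraint after integer rounding")
    deviations, selected, objective = evaluated
    sol = Solution(
        status="optimal",
        counts={v.name: assignment[v.name] for v in m.count_vars.values()},
        binaries={v.name: assignment[v.name] for v in m.binary_vars.values()},
        deviations=deviations,
        objective=objective,
        selected_aspirations=selected,
    )
    violations = check_complementarity(sol, opts.complementarity_tol)
    if violations:
        logger.warning("complementarity violated at optimum: %s", violations)
    return sol


@dataclass
class PlanReport:
    """Per-period solution tables for one model variant."""

    variant: str
    scenario: Scenario
    periods: tuple
    solutions: tuple                       # one Solution per period
    budget_table: pd.DataFrame             # year x budget component costs
    staff_table: pd.DataFrame
    device_table: pd.DataFrame
    drug_table: pd.DataFrame
    deviation_table: pd.DataFrame
    targets: tuple = ()

    def totals(self) -> pd.DataFrame:
        """Per-year aggregates: cost and head/unit counts."""
        rows = []
        for p in self.periods:
            y = p.year
            staff = self.staff_table[self.staff_table.year == y]
            dev = self.device_table[self.device_table.year == y]
            drug = self.drug_table[self.drug_table.year == y]
            sol = self.solutions[list(self.periods).index(p)]
            rows.append({
                "year": y,
                "total_cost": staff.cost.sum() + dev.cost.sum()
                              + drug.cost.sum(),
                "staff_cost": staff.cost.sum(),
                "device_cost": dev.cost.sum(),
                "drug_cost": drug.cost.sum(),
                "total_staff": int(staff["count"].sum()),
                "total_devices": int(dev["count"].sum()),
                "total_drugs": int(drug.quantity.sum()),
                "objective": sol.objective,
            })
        return pd.DataFrame(rows)


def _build_variant(s, targets, variant, cuts, budget_relation):
    if variant == "gp":
        return build_gp(s, targets, budget_relation=budget_relation)
    if variant == "ngp":
        return build_ngp(s, targets, cuts, budget_relation=budget_relation)
    if variant == "nmcgp":
        return build_nmcgp(s, targets, cuts, budget_relation=budget_relation)
    raise ValueError(f"unknown variant {variant!r}")


def plan_horizon(s: Scenario, variant: str = "gp",
                 cuts: CutLevels | None = None,
                 opts: SolverOptions | None = None, *,
                 transfer: str = "off",
                 budget_relation: str = "le",
                 daily_base: float = DEFAULT_DAILY_BASE,
                 daily_slope: float = DEFAULT_DAILY_SLOPE,
                 device_shift_factor: bool = False) -> PlanReport:
    """Build, solve and tabulate the chosen variant for every period."""
    if not s.periods:
        raise PlanningError("scenario has no planning periods")
    if variant in ("ngp", "nmcgp") and cuts is None:
        cuts = DEFAULT_CUT_LEVELS
    opts = opts or SolverOptions()

    solutions, all_targets = [], []
    budget_rows, staff_rows, device_rows, drug_rows, dev_rows = \
        [], [], [], [], []
    for p in s.periods:
        tset = targets_for_period(
            s, p, daily_base=daily_base, daily_slope=daily_slope,
            device_shift_factor=device_shift_factor)
        model = _build_variant(s, tset, variant, cuts, budget_relation)
        model = device_transfer_constraints(model, s, tset, mode=transfer)
        logger.info("solving %s for %s (t=%g)", variant, p.year, p.t)
        sol = solve_model(model, opts)
        if sol.status != "optimal":
            raise PlanningError(
                f"period {p.year} (t={p.t}): solver status {sol.status}")
        solutions.append(sol)
        all_targets.append(tset)

        staff_cost = sum(sol.counts[f"x[{st.name}]"] * st.unit_cost
                         for st in s.staff)
        device_cost = sum(sol.counts[f"y[{dv.name}]"] * dv.unit_cost
                          for dv in s.devices)
        drug_cost = sum(sol.counts[f"z[{dr.name}]"] * dr.unit_price
                        for dr in s.drugs)
        total = staff_cost + device_cost + drug_cost
        comp = {"total_budget": total, "staff_budget": staff_cost,
                "device_budget": device_cost, "drug_budget": drug_cost}
        for label, asp in zip(BUDGET_LABELS, tset.budget_targets):
            realized_asp = sol.selected_aspirations.get(label)
            if realized_asp is None:
                g = model.goal_by_label(label)
                realized_asp = g.aspiration
            budget_rows.append({
                "year": p.year, "budget": label, "cost": comp[label],
                "aspiration": realized_asp,
                "share_pct": 100.0 * comp[label] / total if total else np.nan,
                "neg_dev": sol.deviations[label][0],
                "pos_dev": sol.deviations[label][1],
            })
        n_staff = sum(sol.counts[f"x[{st.name}]"] for st in s.staff)
        for st in s.staff:
            cnt = sol.counts[f"x[{st.name}]"]
            staff_rows.append({
                "year": p.year, "staff": st.name, "count": cnt,
                "share_pct": 100.0 * cnt / n_staff if n_staff else np.nan,
                "cost": cnt * st.unit_cost,
            })
        n_dev = sum(sol.counts[f"y[{dv.name}]"] for dv in s.devices)
        for dv in s.devices:
            cnt = sol.counts[f"y[{dv.name}]"]
            device_rows.append({
                "year": p.year, "device": dv.name, "count": cnt,
                "share_pct": 100.0 * cnt / n_dev if n_dev else np.nan,
                "cost": cnt * dv.unit_cost,
            })
        for dr in s.drugs:
            cnt = sol.counts[f"z[{dr.name}]"]
            drug_rows.append({
                "year": p.year, "drug": dr.name, "quantity": cnt,
                "cost": cnt * dr.unit_price,
            })
        for label, (n, pdev) in sol.deviations.items():
            dev_rows.append({"year": p.year, "goal": label,
                             "neg_dev": n, "pos_dev": pdev})

    return PlanReport(
        variant=variant, scenario=s, periods=tuple(s.periods),
        solutions=tuple(solutions),
        budget_table=pd.DataFrame(budget_rows),
        staff_table=pd.DataFrame(staff_rows),
        device_table=pd.DataFrame(device_rows),
        drug_table=pd.DataFrame(drug_rows),
        deviation_table=pd.DataFrame(dev_rows),
        targets=tuple(all_targets),
    )


def growth_summary(r: PlanReport) -> pd.DataFrame:
    """CAGR and mean period-over-period growth for every planned series.

    Both measures are labeled explicitly; a zero first-period value makes
    growth undefined and is reported as such.
    """
    if len(r.periods) < 2:
        raise ValueError("growth needs at least 2 periods")
    span = r.periods[-1].year - r.periods[0].year

    def one(label, series):
        series = list(series)
        first, last = series[0], series[-1]
        if first == 0:
            return {"series": label, "first": first, "last": last,
                    "cagr_pct": np.nan, "mean_period_growth_pct": np.nan,
                    "note": "undefined: first-period value is zero"}
        cagr = (last / first) ** (1.0 / span) - 1.0
        rel = [series[i + 1] / series[i] - 1.0
               for i in range(len(series) - 1) if series[i] != 0]
        return {"series": label, "first": first, "last": last,
                "cagr_pct": 100.0 * cagr,
                "mean_period_growth_pct": 100.0 * float(np.mean(rel)),
                "note": ""}

    rows = []
    for label in BUDGET_LABELS:
        sub = r.budget_table[r.budget_table.budget == label]
        rows.append(one(label + "_cost", sub.cost.tolist()))
    tot = r.totals()
    for col in ("total_staff", "total_devices", "total_drugs"):
        rows.append(one(col, tot[col].tolist()))
    for dr in r.scenario.drugs:
        sub = r.drug_table[r.drug_table.drug == dr.name]
        rows.append(one(f"drug:{dr.name}", sub.quantity.tolist()))
    return pd.DataFrame(rows)


def compare_variants(reports) -> pd.DataFrame:
    """Cross-model comparison: per-year aggregates for each variant."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to compare")
    years = [p.year for p in reports[0].periods]
    for r in reports[1:]:
        if [p.year for p in r.periods] != years:
            raise ValueError("reports cover different periods")
    rows = []
    metrics = [("total_budget", "total_cost"), ("total_staff", "total_staff"),
               ("total_devices", "total_devices"),
               ("total_medicines", "total_drugs"),
               ("objective", "objective")]
    for metric, col in metrics:
        for r in reports:
            tot = r.totals().set_index("year")[col]
            row = {"metric": metric, "variant": r.variant}
            row.update({int(y): tot.loc[y] for y in years})
            rows.append(row)
    return pd.DataFrame(rows)


def _display_round(df: pd.DataFrame) -> pd.DataFrame:
    """Display conventions: currency to 1 decimal, shares to 0 decimals.

    Raw values are preserved in ``*_raw`` companion columns.
    """
    out = df.copy()
    for col in out.columns:
        if col in ("cost", "aspiration", "neg_dev", "pos_dev"):
            out[col + "_raw"] = out[col]
            out[col] = out[col].round(1)
        elif col == "share_pct":
            out[col + "_raw"] = out[col]
            out[col] = out[col].round(0)
    return out


def write_report(r: PlanReport, out_dir, format: str = "csv") -> list:
    """Write one CSV per table; returns the written paths."""
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "budgets": _display_round(r.budget_table),
        "staff": _display_round(r.staff_table),
        "devices": _display_round(r.device_table),
        "drugs": _display_round(r.drug_table),
        "deviations": _display_round(r.deviation_table),
        "totals": r.totals(),
        "growth": growth_summary(r) if len(r.periods) >= 2 else None,
    }
    for name, df in tables.items():
        if df is None:
            continue
        path = out / f"{r.variant}_{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
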