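"""Seeded synthetic scenarios and a brute-force optimizer oracle.

The generator emulates the structure of the bundled case study: resource
catalogs with per-unit costs and service ratios, base budgets equal to the
base-catalog cost times a slack factor, valid neutrosophic budget forms
built around those crisp values, a patient growth rate and a planning
horizon.  Defaults mirror the case-study conditions (catalog sizes 8/7/40,
cost and ratio ranges spanning the published catalogs, 8% annual growth,
two shifts).

The brute-force oracle enumerates every integer assignment of a tiny model
and computes deviations in closed form; it shares that closed form with
the solver read-back, so solver-vs-oracle agreement checks the MILP
construction, not the bookkeeping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .goals import GoalModel, Solution, evaluate_assignment
from .gtnn import GTNN, CutLevels, validate_gtnn
from .scenario import (
    BudgetSet,
    DeviceType,
    DrugType,
    PlanningPeriod,
    Scenario,
    StaffKind,
    validate_scenario,
)

__all__ = [
    "GeneratorConfig",
    "generate_gtnn",
    "generate_scenario",
    "brute_force_optimum",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ranges for random-scenario generation (all intervals inclusive)."""

    seed: int = 0
    n_staff: int = 8
    n_devices: int = 7
    n_drugs: int = 40
    staff_cost_range: tuple = (2400.0, 9600.0)
    device_cost_range: tuple = (200.0, 9600.0)
    drug_price_range: tuple = (0.1, 420.0)
    ratio_range: tuple = (3.0, 100.0)
    demand_range: tuple = (40, 14000)
    budget_slack: tuple = (1.0, 1.3)
    spread_fraction_range: tuple = (0.02, 0.3)
    w_range: tuple = (0.6, 1.0)
    u_range: tuple = (0.0, 0.5)
    y_range: tuple = (0.0, 0.6)
    growth_rate: float = 0.08
    shifts: int = 2
    horizon: tuple = (0.0, 2.0, 4.0, 8.0)

    def __post_init__(self):
        for name in ("staff_cost_range", "device_cost_range",
                     "drug_price_range", "ratio_range", "demand_range",
                     "budget_slack", "spread_fraction_range",
                     "w_range", "u_range", "y_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if min(self.n_staff, self.n_devices, self.n_drugs) < 1:
            raise ValueError("catalog sizes must be positive")
        if self.w_range[1] + self.u_range[0] + self.y_range[0] > 3:
            raise ValueError("degree ranges admit no valid (w, u, y)")
        if self.w_range[0] <= 0:
            raise ValueError("w must be > 0")


def _draw_gtnn(rng: np.random.Generator, mean: float,
               spread_fraction_range, w_range, u_range, y_range) -> GTNN:
    spreads = rng.uniform(*spread_fraction_range, size=6) * abs(mean)
    w = rng.uniform(*w_range)
    # keep w + u + y <= 3 by construction
    u = rng.uniform(u_range[0], min(u_range[1], 3.0 - w))
    y = rng.uniform(y_range[0], min(y_range[1], 3.0 - w - u))
    g = GTNN(mean, spreads[0], spreads[1], w, spreads[2], spreads[3], u,
             spreads[4], spreads[5], y)
    return validate_gtnn(g)


def generate_gtnn(seed: int, mean_range=(1e4, 1e6),
                  spread_fraction_range=(0.02, 0.3),
                  w_range=(0.6, 1.0), u_range=(0.0, 0.5),
                  y_range=(0.0, 0.6)) -> tuple:
    """One random valid GTNN plus admissible default cut levels.

    Returns ``(gtnn, cut_levels)`` with the levels at mid-admissible
    values: ``alpha = w/2, beta = (1+u)/2, gamma = (1+y)/2``.
    """
    rng = np.random.default_rng(seed)
    mean = rng.uniform(*mean_range)
    g = _draw_gtnn(rng, mean, spread_fraction_range, w_range, u_range,
                   y_range)
    cuts = CutLevels(alpha=g.w / 2, beta=(1 + g.u) / 2, gamma=(1 + g.y) / 2)
    return g, cuts


def generate_scenario(cfg: GeneratorConfig) -> Scenario:
    """A reproducible random scenario satisfying every invariant.

    Crisp base budgets are the base-catalog costs scaled by a slack drawn
    from ``budget_slack``; the neutrosophic budgets are built around those
    crisp values with spreads proportional to the mean.
    """
    rng = np.random.default_rng(cfg.seed)
    staff = [
        StaffKind(
            name=f"staff_{i}",
            unit_cost=round(float(rng.uniform(*cfg.staff_cost_range)), 2),
            patient_ratio=round(float(rng.uniform(*cfg.ratio_range)), 2),
            base_count=int(rng.integers(1, 21)),
        )
        for i in range(cfg.n_staff)
    ]
    devices = [
        DeviceType(
            name=f"device_{j}",
            unit_cost=round(float(rng.uniform(*cfg.device_cost_range)), 2),
            patient_ratio=round(float(rng.uniform(*cfg.ratio_range)), 2),
            base_count=int(rng.integers(1, 11)),
        )
        for j in range(cfg.n_devices)
    ]
    drugs = [
        DrugType(
            name=f"drug_{k}",
            unit_price=round(float(rng.uniform(*cfg.drug_price_range)), 2),
            base_demand=int(rng.integers(cfg.demand_range[0],
                                         cfg.demand_range[1] + 1)),
        )
        for k in range(cfg.n_drugs)
    ]
    staff_cost = sum(s.unit_cost * s.base_count for s in staff)
    device_cost = sum(d.unit_cost * d.base_count for d in devices)
    drug_cost = sum(d.unit_price * d.base_demand for d in drugs)
    slacks = rng.uniform(*cfg.budget_slack, size=3)
    bases = (staff_cost * slacks[0], device_cost * slacks[1],
             drug_cost * slacks[2])
    total = sum(bases)

    def budget(mean):
        return _draw_gtnn(rng, mean, cfg.spread_fraction_range,
                          cfg.w_range, cfg.u_range, cfg.y_range)

    return validate_scenario(Scenario(
        staff=staff, devices=devices, drugs=drugs,
        budgets=BudgetSet(total=budget(total), staff=budget(bases[0]),
                          devices=budget(bases[1]), drugs=budget(bases[2])),
        shifts=cfg.shifts,
        growth_rate=cfg.growth_rate,
        priority_weights=(1.0, 1.0, 1.0, 1.0),
        patient_history=(),
        periods=[PlanningPeriod(2018 + int(t), float(t))
                 for t in cfg.horizon],
    ))


def brute_force_optimum(m: GoalModel, bounds: dict,
                        max_enumeration: int = 10**6) -> Solution:
    """Exact optimum of a tiny model by exhaustive enumeration.

    ``bounds`` maps every count-variable name to an inclusive integer
    upper bound (lower bounds come from the model).  Binaries are
    enumerated over {0, 1}.  Deviations use the same closed form as the
    solver read-back: under soft equality ``n = max(g-f, 0),
    p = max(f-g, 0)``; one-sided goals pay only on the violated side.
    """
    ranges = []
    names = []
    for v in m.count_vars.values():
        if v.name not in bounds:
            raise ValueError(f"no enumeration bound for {v.name}")
        lo = int(math.ceil(v.lb))
        hi = int(bounds[v.name])
        if hi < lo:
            raise ValueError(f"bound for {v.name} is below its floor")
        names.append(v.name)
        ranges.append(range(lo, hi + 1))
    # selection binaries are exclusive within their goal: enumerate them
    # one-hot instead of over the full binary cube
    grouped = set()
    for g in m.goals:
        if g.choice_vars:
            grouped.update(g.choice_vars)
            names.extend(g.choice_vars)
            k = len(g.choice_vars)
            ranges.append([tuple(int(i == j) for i in range(k))
                           for j in range(k)])
    for v in m.binary_vars.values():
        if v.name not in grouped:
            names.append(v.name)
            ranges.append(range(0, 2))
    size = 1
    for r in ranges:
        size *= len(r)
        if size > max_enumeration:
            raise ValueError(
                f"enumeration size exceeds {max_enumeration}")

    def flatten(combo):
        flat = []
        for item in combo:
            if isinstance(item, tuple):
                flat.extend(item)
            else:
                flat.append(item)
        return flat

    best = None
    for combo in itertools.product(*ranges):
        assignment = dict(zip(names, flatten(combo)))
        evaluated = evaluate_assignment(m, assignment)
        if evaluated is None:
            continue
        deviations, selected, objective = evaluated
        if best is None or objective < best[2] - 1e-12:
            best = (assignment, deviations, objective, selected)
    if best is None:
        return Solution(status="infeasible")
    assignment, deviations, objective, selected = best
    return Solution(
        status="optimal",
        counts={v.name: assignment[v.name] for v in m.count_vars.values()},
        binaries={v.name: assignment[v.name] for v in m.binary_vars.values()},
        deviations=deviations,
        objective=objective,
        selected_aspirations=selected,
    )
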