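"""Goal-programming model builders: crisp, neutrosophic, and multi-choice.

All three planning variants share one structure.  Integer decision
variables count staff (``x``), devices (``y``) and drugs (``z``).  Each
resource carries a *goal*: a soft equality tying the count to its
real-valued requirement through a pair of nonnegative deviation variables
``(n, p)``; the requirement is also a hard floor, so a fractional
requirement (142.5 nurses) is met by the next integer and the residue
appears as a small positive deviation.  Four *budget goals* compare the
staff/device/drug/total spend against the period's budget aspiration;
they are one-sided (only overspend is penalized — an under-used budget is
slack, not a planning failure).  The objective minimizes the weighted sum
of all deviations.

The variants differ only in where the budget aspirations come from:

* **GP** — the crisp budgets, grown linearly with the planning horizon;
* **NGP** — the crisp value (average of the three cut midpoints) of each
  neutrosophic budget, then grown identically;
* **NMCGP** — the optimizer itself picks one of the three cut midpoints
  per budget, via three exclusive selection binaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .gtnn import CutLevels, GTNN, crisp_value, cut_midpoints, validate_cut_levels
from .scenario import BudgetSet, Scenario
from .targets import TargetSet, grow_budget

__all__ = [
    "Var",
    "GoalConstraint",
    "HardConstraint",
    "GoalModel",
    "AspirationTriple",
    "Solution",
    "ModelError",
    "BUDGET_LABELS",
    "build_gp",
    "build_ngp",
    "build_nmcgp",
    "crisp_budgets_ngp",
    "multichoice_terms",
    "device_transfer_constraints",
    "goal_deviations",
    "evaluate_assignment",
    "check_complementarity",
    "to_lp",
]

BUDGET_LABELS = ("total_budget", "staff_budget", "device_budget",
                 "drug_budget")


class ModelError(ValueError):
    """Model construction or configuration failure."""


@dataclass
class Var:
    name: str
    integer: bool = True
    lb: float = 0.0
    ub: float | None = None    # None = unbounded above
    binary: bool = False


@dataclass
class GoalConstraint:
    """``f(x) + n - p  <rel>  aspiration (+ selected choice)``.

    For a multi-choice goal, ``choices`` holds the candidate aspiration
    levels and ``choice_vars`` the exclusive selection binaries; the
    realized aspiration is ``aspiration + sum(choices[r] * s_r)`` (the
    constant ``aspiration`` is then an offset, normally 0).
    """

    label: str
    expression: dict          # var name -> coefficient
    relation: str             # "eq" | "le" | "ge"
    aspiration: float
    neg_dev: str
    pos_dev: str
    weight: float = 1.0
    choices: tuple | None = None
    choice_vars: tuple | None = None

    def __post_init__(self):
        if self.relation not in ("eq", "le", "ge"):
            raise ModelError(f"unknown goal relation {self.relation!r}")
        if self.weight < 0:
            raise ModelError("goal weight must be >= 0")
        if (self.choices is None) != (self.choice_vars is None):
            raise ModelError("choices and choice_vars must come together")
        if self.choices is not None and len(self.choices) != len(self.choice_vars):
            raise ModelError("one selection binary per choice is required")


@dataclass
class HardConstraint:
    """``lb <= expression <= ub`` (either bound may be None)."""

    label: str
    expression: dict
    lb: float | None = None
    ub: float | None = None


@dataclass
class GoalModel:
    variant: str
    count_vars: dict = field(default_factory=dict)   # name -> Var
    binary_vars: dict = field(default_factory=dict)
    goals: list = field(default_factory=list)
    hard: list = field(default_factory=list)
    big_m: float | None = None

    def all_vars(self):
        yield from self.count_vars.values()
        yield from self.binary_vars.values()

    def goal_by_label(self, label: str) -> GoalConstraint:
        for g in self.goals:
            if g.label == label:
                return g
        raise KeyError(label)


@dataclass(frozen=True)
class AspirationTriple:
    """The three candidate aspiration levels of one budget."""

    g1: float
    g2: float
    g3: float

    def as_tuple(self) -> tuple:
        return (self.g1, self.g2, self.g3)


@dataclass
class Solution:
    status: str                       # optimal | infeasible | unbounded | ...
    counts: dict = field(default_factory=dict)       # var name -> int
    binaries: dict = field(default_factory=dict)
    deviations: dict = field(default_factory=dict)   # goal label -> (n, p)
    objective: float = float("nan")
    selected_aspirations: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared deviation bookkeeping (single source of truth: used when reading
# back solver output and by the brute-force oracle)

def goal_deviations(relation: str, f_value: float, rhs: float) -> tuple:
    """Optimal ``(n, p)`` for one goal given the achieved value ``f``.

    Both deviations carry positive cost, so at optimality: an equality goal
    has ``n = max(rhs-f, 0), p = max(f-rhs, 0)``; a one-sided goal only
    pays on the violated side.
    """
    if relation == "eq":
        return (max(rhs - f_value, 0.0), max(f_value - rhs, 0.0))
    if relation == "le":
        return (0.0, max(f_value - rhs, 0.0))
    if relation == "ge":
        return (max(rhs - f_value, 0.0), 0.0)
    raise ModelError(f"unknown goal relation {relation!r}")


def _expr_value(expression: dict, assignment: dict) -> float:
    return sum(coef * assignment.get(name, 0) for name, coef in
               expression.items())


def evaluate_assignment(m: GoalModel, assignment: dict,
                        tol: float = 1e-6):
    """Deviations, realized aspirations and objective for a full integer
    assignment of counts and binaries.

    Returns ``None`` if a hard constraint is violated.
    """
    for h in m.hard:
        v = _expr_value(h.expression, assignment)
        if h.lb is not None and v < h.lb - tol:
            return None
        if h.ub is not None and v > h.ub + tol:
            return None
    for var in m.all_vars():
        v = assignment.get(var.name, 0)
        if v < var.lb - tol or (var.ub is not None and v > var.ub + tol):
            return None
    deviations = {}
    selected = {}
    objective = 0.0
    for g in m.goals:
        rhs = g.aspiration
        if g.choices is not None:
            rhs += sum(c * assignment.get(s, 0)
                       for c, s in zip(g.choices, g.choice_vars))
            selected[g.label] = rhs
        f = _expr_value(g.expression, assignment)
        n, p = goal_deviations(g.relation, f, rhs)
        deviations[g.label] = (n, p)
        objective += g.weight * (n + p)
    return deviations, selected, objective


def check_complementarity(sol: Solution, tol: float = 1e-6) -> list:
    """Goals where both deviations are active: ``n * p > tol``."""
    return [(label, n, p) for label, (n, p) in sol.deviations.items()
            if n * p > tol]


# ---------------------------------------------------------------------------
# builders

def _resource_vars_and_goals(s: Scenario, targets: TargetSet):
    count_vars = {}
    goals = []
    cost_total, cost_staff, cost_dev, cost_drug = {}, {}, {}, {}

    def add(prefix, items, raws, ints, cost_attr, cost_map):
        for item, raw, floor in zip(items, raws, ints):
            name = f"{prefix}[{item.name}]"
            if name in count_vars:
                raise ModelError(f"duplicate variable {name}")
            count_vars[name] = Var(name, integer=True, lb=float(floor))
            cost = getattr(item, cost_attr)
            cost_map[name] = cost
            cost_total[name] = cost
            goals.append(GoalConstraint(
                label=name, expression={name: 1.0}, relation="eq",
                aspiration=raw, neg_dev=f"n[{name}]", pos_dev=f"p[{name}]"))

    add("x", s.staff, targets.staff_raw, targets.staff_targets,
        "unit_cost", cost_staff)
    add("y", s.devices, targets.device_raw, targets.device_targets,
        "unit_cost", cost_dev)
    add("z", s.drugs, targets.drug_raw, targets.drug_targets,
        "unit_price", cost_drug)
    return count_vars, goals, (cost_total, cost_staff, cost_dev, cost_drug)


def _build_base(s: Scenario, targets: TargetSet, variant: str,
                budget_aspirations, budget_relation: str,
                budget_choices=None) -> GoalModel:
    if not s.staff or not s.devices or not s.drugs:
        raise ModelError("empty resource catalogs")
    count_vars, goals, cost_maps = _resource_vars_and_goals(s, targets)
    m = GoalModel(variant=variant, count_vars=count_vars)
    weights = s.priority_weights

    budget_goals = []
    for idx, (label, cost_map) in enumerate(zip(BUDGET_LABELS, cost_maps)):
        if budget_choices is None:
            asp = float(budget_aspirations[idx])
            if asp <= 0:
                raise ModelError(f"{label} aspiration must be > 0, got {asp}")
            choices = choice_vars = None
        else:
            asp = 0.0
            choices = tuple(float(c) for c in budget_choices[idx])
            choice_vars = tuple(f"s[{label},{r + 1}]"
                                for r in range(len(choices)))
            for name in choice_vars:
                m.binary_vars[name] = Var(name, integer=True, lb=0, ub=1,
                                          binary=True)
            m.hard.append(HardConstraint(
                label=f"select_one[{label}]",
                expression={name: 1.0 for name in choice_vars},
                lb=1.0, ub=1.0))
        budget_goals.append(GoalConstraint(
            label=label, expression=dict(cost_map),
            relation=budget_relation, aspiration=asp,
            neg_dev=f"n[{label}]", pos_dev=f"p[{label}]",
            weight=float(weights[idx]), choices=choices,
            choice_vars=choice_vars))
    m.goals = budget_goals + goals
    return m


def build_gp(s: Scenario, targets: TargetSet, *,
             budget_relation: str = "le") -> GoalModel:
    """Crisp goal-programming model at the period's dynamic budgets.

    ``budget_relation`` defaults to the one-sided ``"le"`` form (only
    overspend penalized); pass ``"eq"`` to treat a budget shortfall as an
    equally unwanted deviation — note that this makes the optimizer fill
    under-used budgets with extra resources.
    """
    return _build_base(s, targets, "gp", targets.budget_targets,
                       budget_relation)


def crisp_budgets_ngp(b: BudgetSet, c: CutLevels) -> tuple:
    """Deneutrosophied base budgets: crisp value of each budget GTNN."""
    out = []
    for label, g in zip(BUDGET_LABELS, b.gtnn()):
        validate_cut_levels(g, c)
        v = crisp_value(g, c)
        if v <= 0:
            raise ModelError(
                f"crisp {label} is {v} <= 0: planning infeasible")
        out.append(v)
    return tuple(out)


def build_ngp(s: Scenario, targets: TargetSet, c: CutLevels, *,
              budget_relation: str = "le") -> GoalModel:
    """Neutrosophic GP: budget aspirations deneutrosophied, then grown.

    The crisp value is computed once from the base GTNN and the linear
    growth rule is applied per period (growing the spreads proportionally
    would give the same crisp value, so the order is benign).
    """
    base = crisp_budgets_ngp(s.budgets, c)
    t = targets.period.t
    grown = tuple(grow_budget(v, s.growth_rate, t) for v in base)
    return _build_base(s, targets, "ngp", grown, budget_relation)


def multichoice_terms(b: BudgetSet, c: CutLevels) -> dict:
    """Per budget, the three cut midpoints as candidate aspiration levels."""
    out = {}
    for label, g in zip(BUDGET_LABELS, b.gtnn()):
        validate_cut_levels(g, c)
        out[label] = AspirationTriple(*cut_midpoints(g, c))
    return out


def build_nmcgp(s: Scenario, targets: TargetSet, c: CutLevels, *,
                budget_relation: str = "le") -> GoalModel:
    """Neutrosophic multi-choice GP: the optimizer picks one of the three
    cut midpoints per budget.

    The published bilinear binary encoding (products of two binaries with
    the all-zero pair excluded) is linearized exactly by three mutually
    exclusive selection binaries summing to one.  Each candidate level is
    grown per period like any other budget aspiration.
    """
    triples = multichoice_terms(s.budgets, c)
    t = targets.period.t
    choices = [tuple(grow_budget(v, s.growth_rate, t)
                     for v in triples[label].as_tuple())
               for label in BUDGET_LABELS]
    return _build_base(s, targets, "nmcgp", None, budget_relation,
                       budget_choices=choices)


def default_big_m(m: GoalModel, targets: TargetSet) -> float:
    """10x the largest aspiration/target in the model."""
    vals = [abs(g.aspiration) for g in m.goals]
    for g in m.goals:
        if g.choices:
            vals.extend(abs(cv) for cv in g.choices)
    vals.extend(targets.budget_targets)
    vals.extend(targets.staff_targets)
    vals.extend(targets.device_targets)
    vals.extend(targets.drug_targets)
    return 10.0 * max(vals)


def device_transfer_constraints(m: GoalModel, s: Scenario,
                                targets: TargetSet, mode: str = "aggregate",
                                big_m: float | None = None) -> GoalModel:
    """Device-budget transfer block (surplus moves to the staff budget).

    Adds one indicator binary per device: ``delta_j = 1`` iff the planned
    count strictly exceeds its target.  Modes:

    * ``"off"`` — no block (the model is returned unchanged);
    * ``"aggregate"`` — the staff-budget aspiration is raised by the unit
      cost of every device type whose count stayed at target (the surplus
      interpretation of the published narrative);
    * ``"literal"`` — the published per-device spending bands, which pin
      the staff spend to ``TBS + cm_j`` and to ``TBS`` simultaneously for
      every device and are jointly infeasible for heterogeneous device
      costs; kept for fidelity.
    """
    if mode == "off":
        return m
    if mode not in ("aggregate", "literal"):
        raise ModelError(f"unknown transfer mode {mode!r}")
    M = default_big_m(m, targets) if big_m is None else float(big_m)
    max_target = max((*targets.staff_targets, *targets.device_targets,
                      *targets.drug_targets, *targets.budget_targets))
    if M <= max_target + 1:
        raise ModelError(
            f"big_m={M} is not larger than reachable variable values")
    m.big_m = M

    deltas = {}
    for dev, tnm in zip(s.devices, targets.device_targets):
        yname = f"y[{dev.name}]"
        dname = f"delta[{dev.name}]"
        m.binary_vars[dname] = Var(dname, integer=True, lb=0, ub=1,
                                   binary=True)
        deltas[dev.name] = dname
        # delta = 0  =>  y <= TNM
        m.hard.append(HardConstraint(
            label=f"indicator_ub[{dev.name}]",
            expression={yname: 1.0, dname: -M}, ub=float(tnm)))
        # delta = 1  =>  y >= TNM + 1
        m.hard.append(HardConstraint(
            label=f"indicator_lb[{dev.name}]",
            expression={yname: 1.0, dname: -M}, lb=float(tnm) + 1 - M))

    staff_goal = m.goal_by_label("staff_budget")
    staff_cost = {name: coef for name, coef in staff_goal.expression.items()
                  if name.startswith("x[")}
    if mode == "aggregate":
        # aspiration becomes TBS + sum_j cm_j (1 - delta_j); moving the
        # delta terms to the left side keeps the constraint linear
        for dev in s.devices:
            staff_goal.expression[deltas[dev.name]] = dev.unit_cost
        staff_goal.aspiration += sum(dev.unit_cost for dev in s.devices)
        return m
    # literal: per-device bands around the staff-budget aspiration
    if staff_goal.choices is not None:
        raise ModelError("literal transfer mode requires a single-valued "
                         "staff-budget aspiration")
    tbs = staff_goal.aspiration
    for dev in s.devices:
        d = deltas[dev.name]
        # delta=1: TBS + cm_j - M(1-d) <= staff spend <= TBS + cm_j + M(1-d)
        m.hard.append(HardConstraint(
            label=f"transfer_band_lo[{dev.name}]",
            expression={**staff_cost, d: -M}, lb=tbs + dev.unit_cost - M))
        m.hard.append(HardConstraint(
            label=f"transfer_band_hi[{dev.name}]",
            expression={**staff_cost, d: M}, ub=tbs + dev.unit_cost + M))
        # delta=0: TBS - M d <= staff spend <= TBS + M d
        m.hard.append(HardConstraint(
            label=f"transfer_base_lo[{dev.name}]",
            expression={**staff_cost, d: M}, lb=tbs))
        m.hard.append(HardConstraint(
            label=f"transfer_base_hi[{dev.name}]",
            expression={**staff_cost, d: -M}, ub=tbs))
    return m


# ---------------------------------------------------------------------------
# LP-format export (debugging aid)

def _lp_terms(expression: dict, extra: dict | None = None) -> str:
    parts = []
    items = list(expression.items()) + (list(extra.items()) if extra else [])
    for name, coef in items:
        if coef == 0:
            continue
        sign = "+" if coef >= 0 else "-"
        parts.append(f"{sign} {abs(coef):g} {name.replace(' ', '_')}")
    return " ".join(parts) if parts else "0"


def to_lp(m: GoalModel) -> str:
    """Serialize the model in the standard LP text dialect."""
    obj = {}
    for g in m.goals:
        obj[g.neg_dev] = obj.get(g.neg_dev, 0.0) + g.weight
        obj[g.pos_dev] = obj.get(g.pos_dev, 0.0) + g.weight
    lines = ["Minimize", f" obj: {_lp_terms(obj)}", "Subject To"]
    rel = {"eq": "=", "le": "<=", "ge": ">="}
    for i, g in enumerate(m.goals):
        extra = {g.neg_dev: 1.0, g.pos_dev: -1.0}
        if g.choices is not None:
            for cv, sv in zip(g.choices, g.choice_vars):
                extra[sv] = -cv
        lines.append(f" goal{i}: {_lp_terms(g.expression, extra)} "
                     f"{rel[g.relation]} {g.aspiration:g}")
    for i, h in enumerate(m.hard):
        if h.lb is not None and h.ub is not None and h.lb == h.ub:
            lines.append(f" hard{i}: {_lp_terms(h.expression)} = {h.lb:g}")
            continue
        if h.lb is not None:
            lines.append(f" hard{i}a: {_lp_terms(h.expression)} >= {h.lb:g}")
        if h.ub is not None:
            lines.append(f" hard{i}b: {_lp_terms(h.expression)} <= {h.ub:g}")
    lines.append("Bounds")
    for v in m.all_vars():
        name = v.name.replace(" ", "_")
        ub = "+inf" if v.ub is None else f"{v.ub:g}"
        lines.append(f" {v.lb:g} <= {name} <= {ub}")
    for g in m.goals:
        lines.append(f" 0 <= {g.neg_dev.replace(' ', '_')} <= +inf")
        lines.append(f" 0 <= {g.pos_dev.replace(' ', '_')} <= +inf")
    generals = [v.name.replace(" ", "_") for v in m.count_vars.values()]
    binaries = [v.name.replace(" ", "_") for v in m.binary_vars.values()]
    if generals:
        lines.append("Generals")
        lines.append(" " + " ".join(generals))
    if binaries:
        lines.append("Binaries")
        lines.append(" " + " ".join(binaries))
    lines.append("End")
    return "\n".join(lines) + "\n"
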