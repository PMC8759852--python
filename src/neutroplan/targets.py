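"""Patient-trend estimation and per-period aspiration levels.

Demand grows linearly with time: an OLS line fitted to annual patient
totals yields the annual trend, and a daily-patients form ``XP_day(t) =
daily_base + daily_slope * t`` drives the staffing and device targets.
Budgets and drug demand grow by the simple (non-compounded) rule
``value * (1 + GR * t)``.

Integer targets are ceilings of their real-valued formulas.  The ceilings
are evaluated in exact rational arithmetic: binary round-off on products
like ``275 * 3.24`` (= 891 exactly, 891.0000000000001 in floats) would
otherwise shift a target by one unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .scenario import PlanningPeriod, Scenario

__all__ = [
    "TrendFit",
    "TargetSet",
    "fit_patient_trend",
    "xp_day",
    "grow_budget",
    "drug_demand_target",
    "staff_target",
    "device_target",
    "targets_for_period",
]

# The case-study convention for the daily patient load.
DEFAULT_DAILY_BASE = 5.0
DEFAULT_DAILY_SLOPE = 10.0


_SNAP_REL_TOL = Fraction(1, 10**9)


def _frac(x) -> Fraction:
    """Exact rational view of a number (floats taken bit-exactly)."""
    return x if isinstance(x, Fraction) else Fraction(x)


def _ceil_snap(value: Fraction) -> int:
    """Ceiling with a tiny relative snap to the nearest integer.

    A product like ``275 * (1 + 0.08*28)`` is 891 mathematically but
    fractionally above it through the binary representation of 0.08;
    values within 1e-9 (relative) of an integer round to it instead of
    ceiling past it.
    """
    nearest = round(value)
    if abs(value - nearest) <= _SNAP_REL_TOL * max(1, abs(nearest)):
        return int(nearest)
    return math.ceil(value)


def _ceil_exact(*factors) -> int:
    """Ceiling of a product/quotient chain, evaluated rationally.

    ``_ceil_exact(a, b, (c,))`` computes ``ceil(a * b / c)``; bare values
    multiply, 1-tuples divide.
    """
    acc = Fraction(1)
    for f in factors:
        if isinstance(f, tuple):
            acc /= _frac(f[0])
        else:
            acc *= _frac(f)
    return _ceil_snap(acc)


@dataclass(frozen=True)
class TrendFit:
    """An OLS patient trend, annually and per working day."""

    intercept: float      # patients/year at t = 0
    slope: float          # patients/year per year
    daily_base: float     # patients/day at t = 0
    daily_slope: float    # patients/day per year


def fit_patient_trend(annual_totals, t_index,
                      working_days: float = 250.0) -> TrendFit:
    """Ordinary least squares line through ``(t_index, annual_totals)``.

    The daily form divides the annual coefficients by ``working_days``.
    Note the bundled case study does not derive its daily load this way —
    it pins ``XP_day = 5 + 10 t`` as a stated convention (see
    :func:`targets_for_period` defaults).
    """
    y = np.asarray(annual_totals, dtype=float)
    t = np.asarray(t_index, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("annual_totals and t_index must be equal-length 1-D")
    if len(np.unique(t)) < 2:
        raise ValueError("at least 2 distinct time points are required")
    slope, intercept = np.polyfit(t, y, 1)
    return TrendFit(intercept=float(intercept), slope=float(slope),
                    daily_base=float(intercept) / working_days,
                    daily_slope=float(slope) / working_days)


def xp_day(t: float, daily_base: float = DEFAULT_DAILY_BASE,
           daily_slope: float = DEFAULT_DAILY_SLOPE) -> float:
    """Estimated patients per working day after ``t`` years of growth."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return daily_base + daily_slope * t


def grow_budget(base: float, gr: float, t: float) -> float:
    """Dynamic budget target: linear growth ``base * (1 + gr * t)``."""
    if base < 0 or gr < 0 or t < 0:
        raise ValueError("base, gr and t must all be >= 0")
    return base * (1.0 + gr * t)


def drug_demand_target(qd: int, gr: float, t: float) -> int:
    """Projected drug demand ``ceil(qd * (1 + gr*t))``."""
    if qd < 0:
        raise ValueError(f"base demand must be >= 0, got {qd}")
    return _ceil_exact(qd, 1 + _frac(gr) * _frac(t))


def staff_target(sh: int, xpday: float, xr: float) -> int:
    """Staff needed to serve ``xpday`` patients across ``sh`` shifts.

    One member serves ``xr`` patients per shift: ``ceil(sh * xpday / xr)``.
    """
    if sh < 1:
        raise ValueError(f"sh must be >= 1, got {sh}")
    if xr <= 0:
        raise ValueError(f"xr must be > 0, got {xr}")
    return _ceil_exact(sh, xpday, (xr,))


def device_target(xpday: float, yr: float, sh: int = 1) -> int:
    """Devices needed for the daily patient load: ``ceil(sh * xpday / yr)``.

    Devices are shared across shifts by default (``sh = 1``); pass the
    scenario's shift count to apply the same multiplier as for staff.
    """
    if yr <= 0:
        raise ValueError(f"yr must be > 0, got {yr}")
    if sh < 1:
        raise ValueError(f"sh must be >= 1, got {sh}")
    return _ceil_exact(sh, xpday, (yr,))


@dataclass(frozen=True)
class TargetSet:
    """All aspiration levels for one planning period.

    Integer targets are ceilings of the raw real-valued requirements; the
    raw values are kept alongside because the goal models measure
    deviations against them (a ceiling residue like 142.5 -> 143 shows up
    as a legitimate over-achievement of 0.5).
    """

    period: PlanningPeriod
    budget_targets: tuple      # (total, staff, devices, drugs), currency
    staff_targets: tuple       # int per staff kind
    device_targets: tuple      # int per device type
    drug_targets: tuple        # int per drug
    staff_raw: tuple           # real-valued requirements
    device_raw: tuple
    drug_raw: tuple

    def __post_init__(self):
        for name in ("staff", "device", "drug"):
            ints = getattr(self, f"{name}_targets")
            raws = getattr(self, f"{name}_raw")
            for iv, rv in zip(ints, raws):
                if iv < 0 or rv < 0:
                    raise ValueError(f"negative {name} target")
                slack = 1e-8 * max(1.0, abs(rv))
                if not (-slack <= iv - rv < 1 + slack):
                    raise ValueError(
                        f"{name} target {iv} is not the ceiling of {rv}")


def targets_for_period(s: Scenario, p: PlanningPeriod,
                       daily_base: float = DEFAULT_DAILY_BASE,
                       daily_slope: float = DEFAULT_DAILY_SLOPE,
                       device_shift_factor: bool = False,
                       budget_bases=None) -> TargetSet:
    """Assemble all targets for one period.

    ``budget_bases`` overrides the crisp base budgets (used by the
    neutrosophic variants, which substitute deneutrosophied values before
    applying the growth rule).
    """
    xp = xp_day(p.t, daily_base, daily_slope)
    gr = s.growth_rate
    bases = s.budgets.crisp() if budget_bases is None else tuple(budget_bases)
    if len(bases) != 4:
        raise ValueError("exactly four budget bases expected")
    budget_targets = tuple(grow_budget(b, gr, p.t) for b in bases)

    growth = 1 + _frac(gr) * _frac(p.t)
    staff_raw = tuple(float(_frac(s.shifts) * _frac(xp) / _frac(st.patient_ratio))
                      for st in s.staff)
    dev_sh = s.shifts if device_shift_factor else 1
    device_raw = tuple(float(_frac(dev_sh) * _frac(xp) / _frac(dv.patient_ratio))
                       for dv in s.devices)
    drug_raw = tuple(float(_frac(dr.base_demand) * growth) for dr in s.drugs)

    return TargetSet(
        period=p,
        budget_targets=budget_targets,
        staff_targets=tuple(staff_target(s.shifts, xp, st.patient_ratio)
                            for st in s.staff),
        device_targets=tuple(device_target(xp, dv.patient_ratio, sh=dev_sh)
                             for dv in s.devices),
        drug_targets=tuple(drug_demand_target(dr.base_demand, gr, p.t)
                           for dr in s.drugs),
        staff_raw=staff_raw,
        device_raw=device_raw,
        drug_raw=drug_raw,
    )
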