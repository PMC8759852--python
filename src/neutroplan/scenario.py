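"""Planning-scenario data model, bundled case study, and JSON/CSV I/O.

A :class:`Scenario` describes one healthcare facility: catalogs of staff
kinds, medical-device types and drugs (each with a unit cost and, for staff
and devices, a patients-per-unit service ratio), the four budgets (total,
staff, devices, drugs — crisp numbers or GTNNs), the number of work shifts,
an annual patient growth rate, and the planning periods ``(year, t)`` over
which targets are projected.

The bundled :func:`builtin_alamal` scenario is the oncology-center case
study the models were designed around: 8 staff kinds, 7 device types,
40 drugs, neutrosophic budgets, 8% annual patient growth, and nine planning
periods from 2018 (t=0) to 2048 (t=28).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .gtnn import GTNN, validate_gtnn

__all__ = [
    "StaffKind",
    "DeviceType",
    "DrugType",
    "BudgetSet",
    "PlanningPeriod",
    "Scenario",
    "ScenarioError",
    "validate_scenario",
    "load_scenario",
    "write_scenario",
    "builtin_alamal",
]


class ScenarioError(ValueError):
    """Scenario parsing or validation failure."""


@dataclass(frozen=True)
class StaffKind:
    """One staff category: annual unit cost and patients served per member."""

    name: str
    unit_cost: float          # currency per person per year
    patient_ratio: float      # patients one staff member can serve per day
    base_count: int = 0


@dataclass(frozen=True)
class DeviceType:
    name: str
    unit_cost: float          # currency per device
    patient_ratio: float      # patients one device can serve per day
    base_count: int = 0


@dataclass(frozen=True)
class DrugType:
    name: str
    unit_price: float         # currency per dispensing unit
    base_demand: int = 0      # units consumed in the reference year
    dose: str = ""            # descriptive, e.g. "500 mg"
    package_size: float = 0.0  # descriptive (cm^3)


BudgetValue = "float | GTNN"


@dataclass(frozen=True)
class BudgetSet:
    """The four budgets; each entry is a crisp number or a GTNN."""

    total: object
    staff: object
    devices: object
    drugs: object

    _FIELDS = ("total", "staff", "devices", "drugs")

    def entries(self) -> tuple:
        return (self.total, self.staff, self.devices, self.drugs)

    def crisp(self) -> tuple[float, float, float, float]:
        """Crisp base budgets: the mean ``a`` for GTNN entries."""
        return tuple(
            float(b.a) if isinstance(b, GTNN) else float(b)
            for b in self.entries()
        )

    def gtnn(self) -> tuple[GTNN, GTNN, GTNN, GTNN]:
        """All four entries as GTNNs (crisp entries raise)."""
        out = []
        for name, b in zip(self._FIELDS, self.entries()):
            if not isinstance(b, GTNN):
                raise ScenarioError(
                    f"budget '{name}' is crisp; a GTNN is required here")
            out.append(b)
        return tuple(out)

    def has_gtnn(self) -> bool:
        return all(isinstance(b, GTNN) for b in self.entries())


@dataclass(frozen=True)
class PlanningPeriod:
    """A labeled period: ``t`` = years of growth applied since the base."""

    year: int
    t: float


@dataclass(frozen=True)
class Scenario:
    staff: tuple
    devices: tuple
    drugs: tuple
    budgets: BudgetSet
    shifts: int = 2
    growth_rate: float = 0.08
    priority_weights: tuple = (1.0, 1.0, 1.0, 1.0)
    patient_history: tuple = ()       # (label, annual total) pairs
    periods: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "staff", tuple(self.staff))
        object.__setattr__(self, "devices", tuple(self.devices))
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "priority_weights",
                           tuple(self.priority_weights))
        object.__setattr__(self, "patient_history",
                           tuple(tuple(p) for p in self.patient_history))
        object.__setattr__(self, "periods", tuple(self.periods))


def _check_positive(value, what: str):
    if not value > 0:
        raise ScenarioError(f"{what} must be > 0, got {value}")


def validate_scenario(s: Scenario) -> Scenario:
    """Check all catalog, budget and period invariants; return ``s``."""
    if not s.staff or not s.devices or not s.drugs:
        raise ScenarioError("staff, device and drug catalogs must be nonempty")
    seen = set()
    for kind, items in (("staff", s.staff), ("device", s.devices),
                        ("drug", s.drugs)):
        for it in items:
            if it.name in seen:
                raise ScenarioError(f"duplicate resource name: {it.name!r}")
            seen.add(it.name)
    for st in s.staff:
        _check_positive(st.unit_cost, f"staff {st.name!r} unit_cost")
        _check_positive(st.patient_ratio, f"staff {st.name!r} patient_ratio")
        if st.base_count < 0:
            raise ScenarioError(f"staff {st.name!r} base_count must be >= 0")
    for dv in s.devices:
        _check_positive(dv.unit_cost, f"device {dv.name!r} unit_cost")
        _check_positive(dv.patient_ratio, f"device {dv.name!r} patient_ratio")
        if dv.base_count < 0:
            raise ScenarioError(f"device {dv.name!r} base_count must be >= 0")
    for dr in s.drugs:
        _check_positive(dr.unit_price, f"drug {dr.name!r} unit_price")
        if dr.base_demand < 0:
            raise ScenarioError(f"drug {dr.name!r} base_demand must be >= 0")
    for name, b in zip(BudgetSet._FIELDS, s.budgets.entries()):
        if isinstance(b, GTNN):
            validate_gtnn(b)
        else:
            _check_positive(b, f"budget '{name}'")
    if s.shifts < 1:
        raise ScenarioError(f"shifts must be >= 1, got {s.shifts}")
    if s.growth_rate < 0:
        raise ScenarioError(f"growth_rate must be >= 0, got {s.growth_rate}")
    if any(w < 0 for w in s.priority_weights):
        raise ScenarioError("priority weights must be >= 0")
    if len(s.priority_weights) != 4:
        raise ScenarioError("exactly four priority weights expected "
                            "(total, staff, devices, drugs)")
    last = None
    for p in sorted(s.periods, key=lambda p: p.year):
        if p.t < 0:
            raise ScenarioError(f"period {p.year}: t must be >= 0")
        if last is not None and p.t < last:
            raise ScenarioError(
                "period t values must be nondecreasing with year")
        last = p.t
    return s


# ---------------------------------------------------------------------------
# serialization

_SCENARIO_KEYS = {"staff", "devices", "drugs", "budgets", "shifts",
                  "growth_rate", "priority_weights", "patient_history",
                  "periods"}


def _budget_to_json(b) -> object:
    return b.to_dict() if isinstance(b, GTNN) else b


def _budget_from_json(obj, name: str):
    if isinstance(obj, dict):
        return GTNN.from_dict(obj)
    if isinstance(obj, (int, float)):
        return float(obj)
    raise ScenarioError(f"budget '{name}': expected a number or a GTNN "
                        f"object, got {type(obj).__name__}")


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "staff": [{"name": x.name, "unit_cost": x.unit_cost,
                   "patient_ratio": x.patient_ratio,
                   "base_count": x.base_count} for x in s.staff],
        "devices": [{"name": x.name, "unit_cost": x.unit_cost,
                     "patient_ratio": x.patient_ratio,
                     "base_count": x.base_count} for x in s.devices],
        "drugs": [{"name": x.name, "unit_price": x.unit_price,
                   "base_demand": x.base_demand, "dose": x.dose,
                   "package_size": x.package_size} for x in s.drugs],
        "budgets": {k: _budget_to_json(v) for k, v in
                    zip(BudgetSet._FIELDS, s.budgets.entries())},
        "shifts": s.shifts,
        "growth_rate": s.growth_rate,
        "priority_weights": list(s.priority_weights),
        "patient_history": [[lbl, cnt] for lbl, cnt in s.patient_history],
        "periods": [{"year": p.year, "t": p.t} for p in s.periods],
    }


def _row(d: dict, required: dict, optional: dict, where: str) -> dict:
    unknown = set(d) - set(required) - set(optional)
    if unknown:
        raise ScenarioError(f"{where}: unknown keys {sorted(unknown)}")
    out = {}
    for key, conv in required.items():
        if key not in d or (isinstance(d[key], float) and pd.isna(d[key])):
            raise ScenarioError(f"{where}: missing required field {key!r}")
        try:
            out[key] = conv(d[key])
        except (TypeError, ValueError) as e:
            raise ScenarioError(f"{where}: bad value for {key!r}: {e}") from e
    for key, (conv, default) in optional.items():
        raw = d.get(key, default)
        if isinstance(raw, float) and pd.isna(raw):
            raw = default
        out[key] = conv(raw)
    return out


def scenario_from_dict(doc: dict) -> Scenario:
    if not isinstance(doc, dict):
        raise ScenarioError("scenario document must be a JSON object")
    unknown = set(doc) - _SCENARIO_KEYS
    if unknown:
        raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
    missing = {"staff", "devices", "drugs", "budgets"} - set(doc)
    if missing:
        raise ScenarioError(f"missing scenario keys: {sorted(missing)}")

    staff = [StaffKind(**_row(r, {"name": str, "unit_cost": float,
                                  "patient_ratio": float},
                              {"base_count": (int, 0)},
                              f"staff row {i}"))
             for i, r in enumerate(doc["staff"])]
    devices = [DeviceType(**_row(r, {"name": str, "unit_cost": float,
                                     "patient_ratio": float},
                                 {"base_count": (int, 0)},
                                 f"device row {i}"))
               for i, r in enumerate(doc["devices"])]
    drugs = [DrugType(**_row(r, {"name": str, "unit_price": float},
                             {"base_demand": (int, 0), "dose": (str, ""),
                              "package_size": (float, 0.0)},
                             f"drug row {i}"))
             for i, r in enumerate(doc["drugs"])]

    braw = doc["budgets"]
    unknown = set(braw) - set(BudgetSet._FIELDS)
    if unknown:
        raise ScenarioError(f"unknown budget keys: {sorted(unknown)}")
    missing = set(BudgetSet._FIELDS) - set(braw)
    if missing:
        raise ScenarioError(f"missing budget keys: {sorted(missing)}")
    budgets = BudgetSet(**{k: _budget_from_json(braw[k], k)
                           for k in BudgetSet._FIELDS})

    periods = [PlanningPeriod(**_row(r, {"year": int, "t": float}, {},
                                     f"period row {i}"))
               for i, r in enumerate(doc.get("periods", []))]
    history = [(str(lbl), float(cnt))
               for lbl, cnt in doc.get("patient_history", [])]

    return validate_scenario(Scenario(
        staff=staff, devices=devices, drugs=drugs, budgets=budgets,
        shifts=int(doc.get("shifts", 2)),
        growth_rate=float(doc.get("growth_rate", 0.08)),
        priority_weights=tuple(doc.get("priority_weights", (1, 1, 1, 1))),
        patient_history=history, periods=periods,
    ))


def write_scenario(s: Scenario, dest, format: str = "json") -> None:
    """Write a scenario as a single JSON document or a CSV bundle directory."""
    dest = Path(dest)
    if format == "json":
        dest.write_text(json.dumps(scenario_to_dict(s), indent=1),
                        encoding="utf-8")
    elif format == "csv-bundle":
        dest.mkdir(parents=True, exist_ok=True)
        doc = scenario_to_dict(s)
        pd.DataFrame(doc["staff"]).to_csv(dest / "staff.csv", index=False)
        pd.DataFrame(doc["devices"]).to_csv(dest / "devices.csv", index=False)
        pd.DataFrame(doc["drugs"]).to_csv(dest / "drugs.csv", index=False)
        pd.DataFrame(doc["periods"]).to_csv(dest / "periods.csv", index=False)
        meta = {k: doc[k] for k in ("budgets", "shifts", "growth_rate",
                                    "priority_weights", "patient_history")}
        (dest / "budgets.json").write_text(json.dumps(meta, indent=1),
                                           encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def load_scenario(source, format: str = "json") -> Scenario:
    """Load and validate a scenario from JSON text/path or a CSV bundle dir."""
    if format == "json":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as e:
            raise ScenarioError(f"scenario JSON does not parse: {e}") from e
        return scenario_from_dict(doc)
    if format == "csv-bundle":
        d = Path(source)
        for fname in ("staff.csv", "devices.csv", "drugs.csv", "budgets.json"):
            if not (d / fname).exists():
                raise ScenarioError(f"CSV bundle is missing {fname}")
        meta = json.loads((d / "budgets.json").read_text(encoding="utf-8"))
        doc = dict(meta)
        doc["staff"] = pd.read_csv(d / "staff.csv").to_dict("records")
        doc["devices"] = pd.read_csv(d / "devices.csv").to_dict("records")
        doc["drugs"] = pd.read_csv(d / "drugs.csv").to_dict("records")
        if (d / "periods.csv").exists():
            doc["periods"] = pd.read_csv(d / "periods.csv").to_dict("records")
        return scenario_from_dict(doc)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# bundled case study

_ALAMAL_STAFF = [
    # name, annual unit cost ($), patients/day one member serves, 2016 count
    ("oncologists",       9600, 15, 2),
    ("general doctors",   3840, 20, 2),
    ("radiologists",      5760, 10, 1),
    ("pharmacists",       3360, 100, 2),
    ("lab technicians",   3360, 10, 2),
    ("x-ray technicians", 3120, 30, 1),
    ("nurses",            2400, 4, 6),
    ("other staff",       3600, 10, 20),
]

# Device unit costs are the per-type values implied by the case study's
# per-year cost rows (the published catalog merges three imaging devices
# into one cost cell); the service ratios are as published.
_ALAMAL_DEVICES = [
    ("blood test",           4200, 10, 1),
    ("chemistry apparatus",  4800, 30, 1),
    ("oncology indications", 6660, 30, 1),
    ("ultrasonic",           3200, 30, 1),
    ("x-ray",                3200, 30, 1),
    ("mammogram",            3200, 50, 1),
    ("other equipment",       200, 3, 200),
]

_ALAMAL_DRUGS = [
    # name, package cm^3, unit price ($), 2016 demand, dose
    ("Capecitabin",           243.0,    1.18, 13503, "500 mg"),
    ("Cisplatin -1-",         128.0,    1.67, 80,    "10 mg"),
    ("Cisplatin -2-",         212.5,    6.04, 484,   "50 mg"),
    ("Cyclophosphamide -1-",  112.0,    1.1,  1061,  "500 mg"),
    ("Cyclophosphamide -2-",  54.0,     0.7,  1049,  "200 mg"),
    ("Cyclophosphamide -3-",  212.5,    1.61, 366,   "1000 mg"),
    ("Docitaxel -1-",         150.0,    9.69, 610,   "20 mg"),
    ("Docitaxel -2-",         282.6,    18.98, 694,  "80 mg"),
    ("Epirubicin -1-",        37.5,     4.66, 155,   "10 mg"),
    ("Epirubicin -2-",        112.0,    18.7, 605,   "50 mg"),
    ("Letrozole tabl.",       178.5,    0.25, 4535,  "2.5 mg"),
    ("Paclitaxel -1-",        128.0,    31.45, 210,  "150 mg"),
    ("Paclitaxel -2-",        68.25,    14.8, 275,   "100 mg"),
    ("Paclitaxel -3-",        54.0,     6.66, 155,   "30 mg"),
    ("Fluorouracil (5-fu)-1-", 200.0,   0.66, 110,   "250 mg"),
    ("Fluorouracil (5-fu)-2-", 262.5,   1.38, 226,   "500 mg"),
    ("Tamoxifen",             95.0,     0.12, 6374,  "20 mg"),
    ("Thalidomide",           80.325,   1.35, 778,   "100 mg"),
    ("Doxorubcin -1-",        91.875,   5.26, 790,   "50 mg"),
    ("Doxorubcin -2-",        58.5,     1.66, 756,   "10 mg"),
    ("Ifosphamid",            211.75,   4.85, 152,   "1000 mg"),
    ("Zoledronic acid",       58.5,     15.82, 213,  "4 mg"),
    ("Imatinib",              44.0,     1.4,  2575,  "400 mg"),
    ("Biclutamide",           33.8,     0.82, 2002,  "50 mg"),
    ("Carboplatin -1-",       212.5,    35.7, 281,   "450 mg"),
    ("Carboplatin -2-",       128.0,    16.83, 262,  "150 mg"),
    ("Gemcitabin -1-",        128.0,    29.06, 411,  "1000 mg"),
    ("Dacarbazin",            151.875,  13.98, 158,  "500 mg"),
    ("Pazopanib",             332.75,   15.68, 913,  "400 mg"),
    ("Irenotican",            45.0,     16.92, 110,  "40 mg"),
    ("Ca-folinat",            45.0,     2.21, 123,   "50 mg"),
    ("Mesna",                 39.0,     1.23, 786,   "200 mg"),
    ("Vincristine -2-",       34.375,   1.1,  332,   "1 mg"),
    ("Etopside",              112.0,    2.0,  170,   "100 mg"),
    ("Bleomycin",             45.0,     11.78, 240,  "15 mg"),
    ("Vinblastin -1-",        58.5,     5.7,  286,   "10 mg"),
    ("Filgrastim 30U.i",      116.0,    10.34, 2108, "10 mg"),
    ("Fludarabine",           126.0,    68.0, 41,    "50 mg"),
    ("Zoladex",               495.0,    420.0, 52,   "10.8 mg"),
    ("Liposomol Doxorubcin",  210.0,    137.53, 168, "20 mg"),
]

# Neutrosophic budgets: mean, truth spreads & peak, indeterminacy spreads
# & valley, falsity spreads & valley.  The total-budget falsity spreads are
# stored as published even though the left spread exceeds the mean (the
# validator warns about the negative support).
_ALAMAL_GTNN = {
    "total":   (570860, (100000, 200000, 0.9), (30000, 40000, 0.3),
                (800000, 100000, 0.5)),
    "staff":   (135600, (13000, 100000, 0.9), (18000, 15000, 0.3),
                (20000, 30000, 0.5)),
    "devices": (45260, (1000, 5000, 0.9), (9000, 10000, 0.3),
                (10000, 15000, 0.5)),
    "drugs":   (390000, (10000, 100000, 0.9), (20000, 30000, 0.3),
                (15000, 20000, 0.5)),
}

_ALAMAL_PERIODS = [(2018, 0), (2020, 2), (2024, 4), (2028, 8), (2032, 12),
                   (2036, 16), (2040, 20), (2044, 24), (2048, 28)]


def builtin_alamal(printed_doxorubicin_demand: bool = False) -> Scenario:
    """The bundled Al-Amal oncology-center scenario.

    Parameters
    ----------
    printed_doxorubicin_demand : bool
        The base demand of Doxorubcin -1- defaults to 790 units, the value
        consistent with every projected year of the case study's drug plan;
        pass ``True`` to use the 490 printed in the raw drug catalog instead.
    """
    drugs = []
    for name, size, price, qty, dose in _ALAMAL_DRUGS:
        if name == "Doxorubcin -1-" and printed_doxorubicin_demand:
            qty = 490
        drugs.append(DrugType(name=name, unit_price=price, base_demand=qty,
                              dose=dose, package_size=size))

    def mk(key):
        a, (lm, rm, w), (ls, rs, u), (ln, rn, y) = _ALAMAL_GTNN[key]
        return GTNN(a, lm, rm, w, ls, rs, u, ln, rn, y)

    # Note: validating the total-budget GTNN emits the negative-support
    # sanity warning — deliberate, since its falsity spreads are stored
    # exactly as published.
    return validate_scenario(Scenario(
        staff=[StaffKind(n, c, r, b) for n, c, r, b in _ALAMAL_STAFF],
        devices=[DeviceType(n, c, r, b) for n, c, r, b in _ALAMAL_DEVICES],
        drugs=drugs,
        budgets=BudgetSet(total=mk("total"), staff=mk("staff"),
                          devices=mk("devices"), drugs=mk("drugs")),
        shifts=2,
        growth_rate=0.08,
        priority_weights=(1.0, 1.0, 1.0, 1.0),
        patient_history=(("2015", 1809), ("2016", 3589), ("2017", 8861)),
        periods=[PlanningPeriod(y, t) for y, t in _ALAMAL_PERIODS],
    ))
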