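"""Model builders: GP/NGP/NMCGP structure, transfer block, bookkeeping."""

import pytest

from neutroplan import (
    GTNN,
    BudgetSet,
    CutLevels,
    DeviceType,
    DrugType,
    GTNNValidationError,
    ModelError,
    PlanningPeriod,
    Scenario,
    Solution,
    StaffKind,
    build_gp,
    build_ngp,
    build_nmcgp,
    check_complementarity,
    crisp_budgets_ngp,
    device_transfer_constraints,
    multichoice_terms,
    solve_model,
    targets_for_period,
    to_lp,
    validate_scenario,
)
from neutroplan.goals import BUDGET_LABELS, goal_deviations


def degenerate_budget_scenario(s: Scenario) -> Scenario:
    """Same scenario with zero-spread GTNN budgets at the crisp means."""
    crisp = s.budgets.crisp()
    return Scenario(
        staff=s.staff, devices=s.devices, drugs=s.drugs,
        budgets=BudgetSet(*[GTNN.degenerate(v) for v in crisp]),
        shifts=s.shifts, growth_rate=s.growth_rate,
        priority_weights=s.priority_weights,
        patient_history=s.patient_history, periods=s.periods)


@pytest.fixture(scope="module")
def small():
    """A hand-sized scenario with GTNN budgets."""
    def g(a):
        return GTNN(a, 0.1 * a, 0.2 * a, 0.9, 0.05 * a, 0.1 * a, 0.3,
                    0.1 * a, 0.05 * a, 0.5)

    return validate_scenario(Scenario(
        staff=[StaffKind("doc", 900.0, 10.0, 1),
               StaffKind("nurse", 300.0, 4.0, 2)],
        devices=[DeviceType("scanner", 500.0, 20.0, 1)],
        drugs=[DrugType("pill", 2.0, 50), DrugType("vial", 10.0, 10)],
        budgets=BudgetSet(g(3000.0), g(1500.0), g(500.0), g(1000.0)),
        shifts=2, growth_rate=0.1,
        periods=[PlanningPeriod(2020, 0.0), PlanningPeriod(2024, 4.0)],
    ))


# --------------------------------------------------------------------------
# structure

def test_gp_model_structure(alamal):
    ts = targets_for_period(alamal, alamal.periods[-1])
    m = build_gp(alamal, ts)
    assert len(m.count_vars) == 8 + 7 + 40
    assert len(m.goals) == 4 + 8 + 7 + 40
    devs = [g.neg_dev for g in m.goals] + [g.pos_dev for g in m.goals]
    assert len(devs) == len(set(devs)), "deviation variables must be unique"
    for label, w in zip(BUDGET_LABELS, alamal.priority_weights):
        assert m.goal_by_label(label).weight == w


def test_count_floors_are_integer_targets(alamal):
    ts = targets_for_period(alamal, alamal.periods[-1])
    m = build_gp(alamal, ts)
    assert m.count_vars["x[nurses]"].lb == 143
    assert m.count_vars["z[Capecitabin]"].lb == 43750


def test_lp_export_contains_model_sections(small):
    ts = targets_for_period(small, small.periods[0])
    text = to_lp(build_gp(small, ts))
    for section in ("Minimize", "Subject To", "Bounds", "Generals", "End"):
        assert section in text


# --------------------------------------------------------------------------
# deneutrosophied budgets

def test_crisp_budgets_match_midpoint_average(alamal, cuts):
    tb, tbs, tbm, tbd = crisp_budgets_ngp(alamal.budgets, cuts)
    assert tb == pytest.approx(517103.38, abs=0.05)
    assert tbs == pytest.approx(149060.32, abs=0.05)
    assert tbm == pytest.approx(46495.45, abs=0.05)
    assert tbd == pytest.approx(405261.90, abs=0.05)


def test_degenerate_gtnns_deneutrosophy_to_means(alamal, cuts):
    s = degenerate_budget_scenario(alamal)
    assert crisp_budgets_ngp(s.budgets, cuts) == \
        pytest.approx(alamal.budgets.crisp())


def test_multichoice_terms_match_published_pairs(alamal, cuts):
    triples = multichoice_terms(alamal.budgets, cuts)
    expected = {
        "total_budget": (615304.4, 575145.7143),
        "staff_budget": (174266.7, 134314.3),
        "device_budget": (47037.78, 45688.57),
        "drug_budget": (430000.0, 394285.7),
    }
    for label, (g1, g2) in expected.items():
        triple = triples[label]
        assert triple.g1 == pytest.approx(g1, abs=0.05)
        assert triple.g2 == pytest.approx(g2, abs=0.05)


def test_symmetric_spread_budget_has_constant_triple(cuts):
    g = GTNN(800.0, 80, 80, 0.9, 40, 40, 0.3, 60, 60, 0.5)
    b = BudgetSet(g, g, g, g)
    triple = multichoice_terms(b, cuts)["total_budget"]
    assert triple.as_tuple() == (800.0, 800.0, 800.0)


def test_inadmissible_cut_levels_rejected(alamal):
    with pytest.raises(GTNNValidationError):
        crisp_budgets_ngp(alamal.budgets, CutLevels(0.95, 0.9, 0.8))


# --------------------------------------------------------------------------
# variant reductions and selections

def test_ngp_with_degenerate_budgets_equals_gp(small, cuts):
    s = degenerate_budget_scenario(small)
    ts = targets_for_period(s, s.periods[1])
    gp_sol = solve_model(build_gp(s, ts))
    ngp_sol = solve_model(build_ngp(s, ts, cuts))
    assert gp_sol.counts == ngp_sol.counts
    assert gp_sol.objective == pytest.approx(ngp_sol.objective, abs=1e-6)
    for label, (n, p) in gp_sol.deviations.items():
        n2, p2 = ngp_sol.deviations[label]
        assert n == pytest.approx(n2, abs=1e-6)
        assert p == pytest.approx(p2, abs=1e-6)


def test_nmcgp_selects_a_member_of_each_triple(small, cuts):
    ts = targets_for_period(small, small.periods[1])
    m = build_nmcgp(small, ts, cuts)
    sol = solve_model(m)
    assert sol.status == "optimal"
    triples = multichoice_terms(small.budgets, cuts)
    factor = 1 + small.growth_rate * small.periods[1].t
    for label in BUDGET_LABELS:
        chosen = sol.selected_aspirations[label]
        grown = [v * factor for v in triples[label].as_tuple()]
        assert any(chosen == pytest.approx(v) for v in grown)


def test_nmcgp_with_identical_choices_equals_single_choice(small, cuts):
    # all three choices equal -> same optimum as the single-valued model
    s = degenerate_budget_scenario(small)
    ts = targets_for_period(s, s.periods[1])
    nm = solve_model(build_nmcgp(s, ts, cuts))
    ngp = solve_model(build_ngp(s, ts, cuts))
    assert nm.counts == ngp.counts
    assert nm.objective == pytest.approx(ngp.objective, abs=1e-9)


# --------------------------------------------------------------------------
# device transfer block

def test_transfer_off_returns_model_unchanged(small):
    ts = targets_for_period(small, small.periods[0])
    m = build_gp(small, ts)
    n_goals, n_hard = len(m.goals), len(m.hard)
    m2 = device_transfer_constraints(m, small, ts, mode="off")
    assert m2 is m and len(m2.goals) == n_goals and len(m2.hard) == n_hard


def test_indicator_binary_tracks_target_exceedance(small):
    ts = targets_for_period(small, small.periods[0])
    tnm = ts.device_targets[0]

    m = build_gp(small, ts)
    device_transfer_constraints(m, small, ts, mode="aggregate")
    sol = solve_model(m)
    assert sol.counts["y[scanner]"] == tnm
    assert sol.binaries["delta[scanner]"] == 0

    # force the count above target: the indicator must flip
    m2 = build_gp(small, ts)
    device_transfer_constraints(m2, small, ts, mode="aggregate")
    m2.count_vars["y[scanner]"].lb = tnm + 1
    sol2 = solve_model(m2)
    assert sol2.counts["y[scanner]"] == tnm + 1
    assert sol2.binaries["delta[scanner]"] == 1


def test_aggregate_mode_raises_staff_aspiration_by_unspent_devices(small):
    ts = targets_for_period(small, small.periods[0])
    m = build_gp(small, ts)
    device_transfer_constraints(m, small, ts, mode="aggregate")
    g = m.goal_by_label("staff_budget")
    assert g.aspiration == pytest.approx(
        ts.budget_targets[1] + sum(d.unit_cost for d in small.devices))
    assert g.expression["delta[scanner]"] == small.devices[0].unit_cost


def test_literal_mode_with_two_devices_is_jointly_infeasible():
    # both devices pin the staff spend to TBS (delta=0) while any integer
    # staff mix cannot hit the aspiration exactly -> infeasible by design
    s = validate_scenario(Scenario(
        staff=[StaffKind("doc", 900.0, 10.0, 1)],
        devices=[DeviceType("a", 500.0, 20.0, 1),
                 DeviceType("b", 700.0, 25.0, 1)],
        drugs=[DrugType("pill", 2.0, 10)],
        budgets=BudgetSet(3000.0, 1234.5, 1200.0, 500.0),
        shifts=1, growth_rate=0.0,
        periods=[PlanningPeriod(2020, 0.0)],
    ))
    ts = targets_for_period(s, s.periods[0])
    m = build_gp(s, ts)
    device_transfer_constraints(m, s, ts, mode="literal")
    assert solve_model(m).status == "infeasible"


def test_big_m_too_small_rejected(small):
    ts = targets_for_period(small, small.periods[0])
    m = build_gp(small, ts)
    with pytest.raises(ModelError, match="big_m"):
        device_transfer_constraints(m, small, ts, mode="aggregate",
                                    big_m=1.0)


# --------------------------------------------------------------------------
# deviation bookkeeping

@pytest.mark.parametrize(
    "relation, f, g, expected",
    [
        ("eq", 7.0, 10.0, (3.0, 0.0)),
        ("eq", 12.0, 10.0, (0.0, 2.0)),
        ("le", 7.0, 10.0, (0.0, 0.0)),
        ("le", 12.0, 10.0, (0.0, 2.0)),
        ("ge", 7.0, 10.0, (3.0, 0.0)),
        ("ge", 12.0, 10.0, (0.0, 0.0)),
    ],
)
def test_goal_deviation_closed_form(relation, f, g, expected):
    assert goal_deviations(relation, f, g) == expected


def test_complementarity_flags_hand_built_violation():
    sol = Solution(status="optimal", deviations={"g": (1.0, 1.0)})
    assert check_complementarity(sol) == [("g", 1.0, 1.0)]


def test_optimum_satisfies_complementarity(alamal):
    ts = targets_for_period(alamal, alamal.periods[-1])
    sol = solve_model(build_gp(alamal, ts))
    assert check_complementarity(sol, tol=1e-6) == []
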