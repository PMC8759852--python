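"""Neutrosophic number core: memberships, cuts, midpoints, crisp values."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from neutroplan import (
    GTNN,
    CutLevels,
    GTNNValidationError,
    crisp_value,
    cut_interval,
    cut_midpoints,
    membership_degrees,
    min_of_cuts,
    validate_gtnn,
)

# the four budget GTNNs of the bundled case study
TB = GTNN(570860, 100000, 200000, 0.9, 30000, 40000, 0.3, 800000, 100000, 0.5)
TBS = GTNN(135600, 13000, 100000, 0.9, 18000, 15000, 0.3, 20000, 30000, 0.5)
TBM = GTNN(45260, 1000, 5000, 0.9, 9000, 10000, 0.3, 10000, 15000, 0.5)
TBD = GTNN(390000, 10000, 100000, 0.9, 20000, 30000, 0.3, 15000, 20000, 0.5)

LEVELS = CutLevels(0.1, 0.9, 0.8)


# --------------------------------------------------------------------------
# validation

@pytest.mark.parametrize("g", [TBS, TBM, TBD])
def test_case_study_budgets_are_valid(g):
    assert validate_gtnn(g) is g


def test_negative_support_warns_but_validates():
    # the total-budget falsity left spread exceeds the mean as published
    with pytest.warns(UserWarning, match="support extending below zero"):
        assert validate_gtnn(TB) is TB


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(w=1.2), "w <= 1"),
        (dict(w=0.0), "w must be > 0"),
        (dict(u=-0.1), "u <= 1"),
        (dict(y=2.0), "y <= 1"),
        (dict(l_mu=-1.0), "l_mu"),
    ],
)
def test_invalid_parameters_rejected(kwargs, match):
    base = dict(a=100, l_mu=10, r_mu=10, w=0.9, l_sigma=10, r_sigma=10,
                u=0.3, l_nu=10, r_nu=10, y=0.5)
    base.update(kwargs)
    with pytest.raises(GTNNValidationError, match=match):
        validate_gtnn(GTNN(**base))


def test_degree_sum_boundary_is_valid():
    g = GTNN(100, 10, 10, 1.0, 10, 10, 1.0, 10, 10, 1.0)  # w+u+y = 3
    assert validate_gtnn(g) is g


# --------------------------------------------------------------------------
# membership functions

def test_membership_at_mean_returns_peak_degrees():
    d = membership_degrees(TB, TB.a)
    assert (d.truth, d.indeterminacy, d.falsity) == (0.9, 0.3, 0.5)


@pytest.mark.parametrize(
    "x, truth",
    [
        (470860, 0.0),            # left support boundary a - l_mu
        (670860, 0.45),           # halfway down the right branch: w/2
        (770861, 0.0),            # just past the right support
    ],
)
def test_truth_branch_is_w_scaled(x, truth):
    assert membership_degrees(TB, x).truth == pytest.approx(truth, abs=1e-6)


def test_outside_support_indeterminacy_and_falsity_are_one():
    d = membership_degrees(TBM, TBM.a - 1e6)
    assert d.indeterminacy == 1.0
    assert d.falsity == 1.0


def test_zero_spread_point_mass_convention():
    g = GTNN.degenerate(50.0)
    at = membership_degrees(g, 50.0)
    assert (at.truth, at.indeterminacy, at.falsity) == (1.0, 0.0, 0.0)
    off = membership_degrees(g, 49.0)
    assert (off.truth, off.indeterminacy, off.falsity) == (0.0, 1.0, 1.0)


# --------------------------------------------------------------------------
# cut intervals

def test_truth_cut_interval_alpha_01():
    iv = cut_interval(TB, "truth", 0.1)
    assert iv.lo == pytest.approx(481971.11, abs=0.01)
    assert iv.hi == pytest.approx(748637.78, abs=0.01)
    # its midpoint is the first deneutrosophication component
    assert iv.midpoint == pytest.approx(615304.4, abs=0.05)


def test_truth_cut_at_peak_degenerates_to_mean():
    iv = cut_interval(TB, "truth", 0.9)
    assert iv.lo == pytest.approx(TB.a)
    assert iv.hi == pytest.approx(TB.a)


def test_indeterminacy_cut_at_one_is_full_support():
    iv = cut_interval(TBD, "indeterminacy", 1.0)
    assert (iv.lo, iv.hi) == (370000, 420000)


def test_cut_level_out_of_range_raises():
    with pytest.raises(GTNNValidationError):
        cut_interval(TB, "truth", 0.95)          # above w
    with pytest.raises(GTNNValidationError):
        cut_interval(TB, "indeterminacy", 0.1)   # below u
    with pytest.raises(ValueError, match="kind"):
        cut_interval(TB, "unknown", 0.5)


def test_valley_degree_one_cut_divides_by_zero():
    g = GTNN(100, 10, 10, 0.9, 10, 10, 1.0, 10, 10, 0.5)
    with pytest.raises(ZeroDivisionError):
        cut_interval(g, "indeterminacy", 0.99)
    # level exactly 1 is still well defined
    assert cut_interval(g, "indeterminacy", 1.0).lo == 90


# --------------------------------------------------------------------------
# midpoints and crisp values (deneutrosophication)

@pytest.mark.parametrize(
    "g, mid_alpha, mid_beta",
    [
        (TB, 615304.4, 575145.7143),
        (TBS, 174266.7, 134314.3),
        (TBM, 47037.78, 45688.57),
        (TBD, 430000.0, 394285.7),
    ],
)
def test_cut_midpoints_match_published_deneutrosophication(g, mid_alpha,
                                                           mid_beta):
    ma, mb, _ = cut_midpoints(g, LEVELS)
    assert ma == pytest.approx(mid_alpha, abs=0.05)
    assert mb == pytest.approx(mid_beta, abs=0.05)


def test_symmetric_spreads_give_mean_midpoints():
    g = GTNN(1000, 50, 50, 0.8, 30, 30, 0.2, 40, 40, 0.4)
    assert cut_midpoints(g, CutLevels(0.3, 0.7, 0.9)) == (1000, 1000, 1000)


def test_crisp_value_of_degenerate_gtnn_is_mean():
    assert crisp_value(GTNN.degenerate(1234.5), CutLevels(0.5, 0.5, 0.5)) \
        == 1234.5


@pytest.mark.parametrize("g, expected", [(TB, 517103.38), (TBS, 149060.32)])
def test_crisp_value_frozen_examples(g, expected):
    assert crisp_value(g, LEVELS) == pytest.approx(expected, abs=0.05)


@pytest.mark.parametrize("g", [TB, TBS, TBM, TBD])
def test_crisp_value_equals_interval_midpoint_average(g):
    # independent oracle: midpoints taken from the cut intervals themselves
    mids = [cut_interval(g, "truth", LEVELS.alpha).midpoint,
            cut_interval(g, "indeterminacy", LEVELS.beta).midpoint,
            cut_interval(g, "falsity", LEVELS.gamma).midpoint]
    assert crisp_value(g, LEVELS) == pytest.approx(sum(mids) / 3, rel=1e-12)


@pytest.mark.parametrize("g", [TB, TBS, TBM, TBD])
def test_crisp_value_matches_expanded_closed_form(g):
    c = LEVELS
    expanded = (g.a
                + (g.r_mu - g.l_mu) / 6 * (1 - c.alpha / g.w)
                + (g.r_sigma - g.l_sigma) / 6 * (c.beta - g.u) / (1 - g.u)
                + (g.r_nu - g.l_nu) / 6 * (c.gamma - g.y) / (1 - g.y))
    assert crisp_value(g, c) == pytest.approx(expanded, rel=1e-12)


def test_min_of_cuts_is_elementwise_minimum():
    iv = min_of_cuts(TBM, LEVELS)
    parts = [cut_interval(TBM, "truth", LEVELS.alpha),
             cut_interval(TBM, "indeterminacy", LEVELS.beta),
             cut_interval(TBM, "falsity", LEVELS.gamma)]
    assert iv.lo == min(p.lo for p in parts)
    assert iv.hi == min(p.hi for p in parts)


# --------------------------------------------------------------------------
# randomized invariants

@st.composite
def gtnns(draw):
    a = draw(st.floats(10, 1e6))
    spreads = [draw(st.floats(0.01, 0.5)) * a for _ in range(6)]
    w = draw(st.floats(0.05, 1.0))
    u = draw(st.floats(0.0, 0.95))
    y = draw(st.floats(0.0, 0.95))
    assume(w + u + y <= 3.0)
    return GTNN(a, spreads[0], spreads[1], w, spreads[2], spreads[3], u,
                spreads[4], spreads[5], y)


@st.composite
def gtnn_and_levels(draw):
    g = draw(gtnns())
    fa = draw(st.floats(0.0, 1.0))
    fb = draw(st.floats(0.0, 1.0))
    fc = draw(st.floats(0.0, 1.0))
    return g, CutLevels(alpha=fa * g.w, beta=g.u + fb * (1 - g.u),
                        gamma=g.y + fc * (1 - g.y))


@given(gtnn_and_levels(), st.floats(0.0, 1.0))
def test_cuts_are_nested(gl, frac):
    g, c = gl
    lo_level = c.alpha * frac
    outer = cut_interval(g, "truth", lo_level)
    inner = cut_interval(g, "truth", c.alpha)
    assert outer.lo <= inner.lo + 1e-9 and inner.hi <= outer.hi + 1e-9
    # indeterminacy/falsity shrink as the level decreases toward the valley
    lo_beta = g.u + (c.beta - g.u) * frac
    outer_b = cut_interval(g, "indeterminacy", c.beta)
    inner_b = cut_interval(g, "indeterminacy", lo_beta)
    assert outer_b.lo <= inner_b.lo + 1e-9 and inner_b.hi <= outer_b.hi + 1e-9


@given(gtnn_and_levels())
def test_midpoints_are_interval_means(gl):
    g, c = gl
    ma, mb, mc = cut_midpoints(g, c)
    assert ma == pytest.approx(
        cut_interval(g, "truth", c.alpha).midpoint, rel=1e-9)
    assert mb == pytest.approx(
        cut_interval(g, "indeterminacy", c.beta).midpoint, rel=1e-9)
    assert mc == pytest.approx(
        cut_interval(g, "falsity", c.gamma).midpoint, rel=1e-9)
    assert crisp_value(g, c) == pytest.approx((ma + mb + mc) / 3, rel=1e-12)


@given(gtnn_and_levels())
def test_valley_level_midpoints_equal_mean(gl):
    g, _ = gl
    c = CutLevels(alpha=g.w, beta=g.u, gamma=g.y)
    ma, mb, mc = cut_midpoints(g, c)
    assert ma == pytest.approx(g.a, rel=1e-9)
    assert mb == pytest.approx(g.a, rel=1e-9)
    assert mc == pytest.approx(g.a, rel=1e-9)


@given(gtnn_and_levels())
def test_membership_at_truth_cut_endpoints_recovers_level(gl):
    g, c = gl
    alpha = c.alpha
    assume(0 < alpha < g.w)
    assume(g.l_mu > 1e-6 and g.r_mu > 1e-6)
    iv = cut_interval(g, "truth", alpha)
    assert membership_degrees(g, iv.lo).truth == pytest.approx(alpha,
                                                               abs=1e-6)
    assert membership_degrees(g, iv.hi).truth == pytest.approx(alpha,
                                                               abs=1e-6)
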