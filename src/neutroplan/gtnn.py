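"""Generalized triangular neutrosophic numbers (GTNNs).

A GTNN models an imprecise quantity (here: a budget) through three triangular
membership profiles around a common mean ``a``:

* **truth** — rises from 0 at ``a - l_mu`` to the peak degree ``w`` at ``a``
  and falls back to 0 at ``a + r_mu``;
* **indeterminacy** — dips to its minimum ``u`` at ``a`` and is 1 outside
  the support ``[a - l_sigma, a + r_sigma]``;
* **falsity** — dips to its minimum ``y`` at ``a`` and is 1 outside
  ``[a - l_nu, a + r_nu]``.

The degrees are independent; the only coupling is ``0 <= w + u + y <= 3``.

Cutting each profile at a chosen level yields a closed interval.  The
midpoints of the three intervals are the basic crisp summaries used by the
planning models: averaged (``crisp_value``) for the single-valued route, or
offered as a three-way choice to the optimizer for the multi-choice route.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "GTNN",
    "CutLevels",
    "Interval",
    "MembershipDegrees",
    "GTNNValidationError",
    "validate_gtnn",
    "validate_cut_levels",
    "membership_degrees",
    "cut_interval",
    "cut_midpoints",
    "crisp_value",
    "min_of_cuts",
]


class GTNNValidationError(ValueError):
    """A GTNN or cut-level parameter violates its defining inequalities."""


@dataclass(frozen=True)
class GTNN:
    """A generalized triangular neutrosophic number.

    Parameters
    ----------
    a : float
        Mean value (currency units in the planning context).
    l_mu, r_mu : float
        Left/right spreads of the truth profile (nonnegative).
    w : float
        Maximum truth degree at ``x = a``, in ``(0, 1]``.
    l_sigma, r_sigma : float
        Left/right spreads of the indeterminacy profile.
    u : float
        Minimum indeterminacy degree at ``x = a``, in ``[0, 1]``.
    l_nu, r_nu : float
        Left/right spreads of the falsity profile.
    y : float
        Minimum falsity degree at ``x = a``, in ``[0, 1]``.
    """

    a: float
    l_mu: float
    r_mu: float
    w: float
    l_sigma: float
    r_sigma: float
    u: float
    l_nu: float
    r_nu: float
    y: float

    def is_degenerate(self) -> bool:
        """True when all six spreads are zero (a crisp point at ``a``)."""
        return (
            self.l_mu == self.r_mu == self.l_sigma == self.r_sigma
            == self.l_nu == self.r_nu == 0.0
        )

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "l_mu": self.l_mu, "r_mu": self.r_mu, "w": self.w,
            "l_sigma": self.l_sigma, "r_sigma": self.r_sigma, "u": self.u,
            "l_nu": self.l_nu, "r_nu": self.r_nu, "y": self.y,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GTNN":
        keys = {"a", "l_mu", "r_mu", "w", "l_sigma", "r_sigma", "u",
                "l_nu", "r_nu", "y"}
        unknown = set(d) - keys
        if unknown:
            raise GTNNValidationError(
                f"unknown GTNN keys: {sorted(unknown)}")
        missing = keys - set(d)
        if missing:
            raise GTNNValidationError(
                f"missing GTNN keys: {sorted(missing)}")
        return validate_gtnn(cls(**{k: float(d[k]) for k in keys}))

    @classmethod
    def degenerate(cls, a: float) -> "GTNN":
        """A crisp value embedded as a zero-spread GTNN."""
        return cls(a, 0, 0, 1.0, 0, 0, 0.0, 0, 0, 0.0)


@dataclass(frozen=True)
class CutLevels:
    """Cut levels ``(alpha, beta, gamma)`` for the three profiles."""

    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class MembershipDegrees:
    truth: float
    indeterminacy: float
    falsity: float


def validate_gtnn(g: GTNN) -> GTNN:
    """Check the defining inequalities of a GTNN; return it unchanged.

    Raises
    ------
    GTNNValidationError
        naming the violated inequality.
    """
    for name in ("l_mu", "r_mu", "l_sigma", "r_sigma", "l_nu", "r_nu"):
        if getattr(g, name) < 0:
            raise GTNNValidationError(f"spread {name} must be >= 0, got "
                                      f"{getattr(g, name)}")
    if not 0.0 <= g.w <= 1.0:
        raise GTNNValidationError(f"0 <= w <= 1 violated: w={g.w}")
    if g.w == 0.0:
        raise GTNNValidationError("w must be > 0 (truth cuts divide by w)")
    if not 0.0 <= g.u <= 1.0:
        raise GTNNValidationError(f"0 <= u <= 1 violated: u={g.u}")
    if not 0.0 <= g.y <= 1.0:
        raise GTNNValidationError(f"0 <= y <= 1 violated: y={g.y}")
    if not 0.0 <= g.w + g.u + g.y <= 3.0:
        raise GTNNValidationError(
            f"0 <= w+u+y <= 3 violated: sum={g.w + g.u + g.y}")
    if g.a > 0 and min(g.a - g.l_mu, g.a - g.l_sigma, g.a - g.l_nu) < 0:
        # Not an error: the membership math is well defined on negative
        # support, but for a budget it usually signals a typo in the spreads.
        warnings.warn(
            f"GTNN with mean {g.a} has a support extending below zero "
            "(left spread exceeds the mean); check the spread data",
            UserWarning,
            stacklevel=2,
        )
    return g


def validate_cut_levels(g: GTNN, c: CutLevels) -> CutLevels:
    """Check that cut levels are admissible for ``g``."""
    if not 0.0 <= c.alpha <= g.w:
        raise GTNNValidationError(
            f"alpha must lie in [0, w]=[0, {g.w}], got {c.alpha}")
    if not g.u <= c.beta <= 1.0:
        raise GTNNValidationError(
            f"beta must lie in [u, 1]=[{g.u}, 1], got {c.beta}")
    if not g.y <= c.gamma <= 1.0:
        raise GTNNValidationError(
            f"gamma must lie in [y, 1]=[{g.y}, 1], got {c.gamma}")
    if c.alpha + c.beta + c.gamma > 3.0:
        raise GTNNValidationError(
            f"alpha+beta+gamma <= 3 violated: "
            f"sum={c.alpha + c.beta + c.gamma}")
    return c


def membership_degrees(g: GTNN, x: float) -> MembershipDegrees:
    """Evaluate the three piecewise-linear membership profiles at ``x``.

    The truth branches are scaled by the peak degree ``w`` so that the
    profile and the alpha-cut are mutually inverse (the cut formulas divide
    by ``w``).  Zero-spread branches degenerate to a point mass at ``a``:
    the peak/valley degree exactly at ``x = a``, the outside value elsewhere.
    """
    validate_gtnn(g)

    # truth: 0 outside support, w at the peak
    if x == g.a:
        truth = g.w
    elif g.a - g.l_mu <= x < g.a and g.l_mu > 0:
        truth = g.w * (x - g.a + g.l_mu) / g.l_mu
    elif g.a < x <= g.a + g.r_mu and g.r_mu > 0:
        truth = g.w * (g.a + g.r_mu - x) / g.r_mu
    else:
        truth = 0.0

    # indeterminacy: u at the valley, 1 outside support
    if x == g.a:
        ind = g.u
    elif g.a - g.l_sigma <= x < g.a and g.l_sigma > 0:
        ind = (g.a - x + g.u * (x - g.a + g.l_sigma)) / g.l_sigma
    elif g.a < x <= g.a + g.r_sigma and g.r_sigma > 0:
        ind = (x - g.a + g.u * (g.a + g.r_sigma - x)) / g.r_sigma
    else:
        ind = 1.0

    # falsity: same shape as indeterminacy with y and the nu-spreads
    if x == g.a:
        fal = g.y
    elif g.a - g.l_nu <= x < g.a and g.l_nu > 0:
        fal = (g.a - x + g.y * (x - g.a + g.l_nu)) / g.l_nu
    elif g.a < x <= g.a + g.r_nu and g.r_nu > 0:
        fal = (x - g.a + g.y * (g.a + g.r_nu - x)) / g.r_nu
    else:
        fal = 1.0

    return MembershipDegrees(truth, ind, fal)


_KINDS = ("truth", "indeterminacy", "falsity")


def cut_interval(g: GTNN, kind: str, level: float) -> Interval:
    """The closed interval obtained by cutting one profile at ``level``.

    * ``truth``: values with truth degree >= level (level in ``[0, w]``);
    * ``indeterminacy``: indeterminacy degree <= level (level in ``[u, 1]``);
    * ``falsity``: falsity degree <= level (level in ``[y, 1]``).
    """
    validate_gtnn(g)
    if kind == "truth":
        if not 0.0 <= level <= g.w:
            raise GTNNValidationError(
                f"truth cut level must lie in [0, {g.w}], got {level}")
        lo = g.a - g.l_mu + level * g.l_mu / g.w
        hi = g.a + g.r_mu - level * g.r_mu / g.w
        return Interval(lo, hi)
    if kind == "indeterminacy":
        lo_spread, hi_spread, floor = g.l_sigma, g.r_sigma, g.u
    elif kind == "falsity":
        lo_spread, hi_spread, floor = g.l_nu, g.r_nu, g.y
    else:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    if level == 1.0:
        # full support; well defined even when the valley degree is 1
        return Interval(g.a - lo_spread, g.a + hi_spread)
    if floor == 1.0:
        raise ZeroDivisionError(
            f"{kind} cut with valley degree 1 is only defined at level 1")
    if not floor <= level <= 1.0:
        raise GTNNValidationError(
            f"{kind} cut level must lie in [{floor}, 1], got {level}")
    scale = (1.0 - level) / (1.0 - floor)
    return Interval(g.a - lo_spread + scale * lo_spread,
                    g.a + hi_spread - scale * hi_spread)


def cut_midpoints(g: GTNN, c: CutLevels) -> tuple[float, float, float]:
    """Midpoints of the three cut intervals, in closed form.

    ``mid_alpha = a + (r_mu - l_mu)/2 * (1 - alpha/w)`` and analogously for
    the indeterminacy and falsity profiles with factors ``(beta-u)/(1-u)``
    and ``(gamma-y)/(1-y)``.  Each equals the arithmetic midpoint of the
    corresponding :func:`cut_interval`.
    """
    validate_gtnn(g)
    validate_cut_levels(g, c)
    mid_a = g.a + 0.5 * (g.r_mu - g.l_mu) * (1.0 - c.alpha / g.w)
    if c.beta == 1.0:
        mid_b = g.a + 0.5 * (g.r_sigma - g.l_sigma)
    elif g.u == 1.0:
        raise ZeroDivisionError(
            "indeterminacy cut with valley degree 1 is only defined at 1")
    else:
        mid_b = g.a + 0.5 * (g.r_sigma - g.l_sigma) * (c.beta - g.u) / (1.0 - g.u)
    if c.gamma == 1.0:
        mid_c = g.a + 0.5 * (g.r_nu - g.l_nu)
    elif g.y == 1.0:
        raise ZeroDivisionError(
            "falsity cut with valley degree 1 is only defined at 1")
    else:
        mid_c = g.a + 0.5 * (g.r_nu - g.l_nu) * (c.gamma - g.y) / (1.0 - g.y)
    return (mid_a, mid_b, mid_c)


def crisp_value(g: GTNN, c: CutLevels) -> float:
    """Single-valued summary: the average of the three cut midpoints."""
    mid_a, mid_b, mid_c = cut_midpoints(g, c)
    return (mid_a + mid_b + mid_c) / 3.0


def min_of_cuts(g: GTNN, c: CutLevels) -> Interval:
    """Elementwise minimum of the three cut intervals.

    Derived utility only — the planning models use :func:`crisp_value`
    (average of midpoints) or the midpoint triple, never this set.
    """
    ia = cut_interval(g, "truth", c.alpha)
    ib = cut_interval(g, "indeterminacy", c.beta)
    ic = cut_interval(g, "falsity", c.gamma)
    return Interval(min(ia.lo, ib.lo, ic.lo), min(ia.hi, ib.hi, ic.hi))
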