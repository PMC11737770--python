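"""Median interval and four exact confidence intervals for the affinity.

All constructions invert the family of equal-tailed exact tests based on
the Extended Hypergeometric distribution function F(x, alpha), which is
strictly decreasing in alpha for interior x:

* quantile (median) interval: alpha values for which the observed count is
  a valid q-quantile: ``(F(x-1,.)^-1(q), F(x,.)^-1(q))``;
* CP: Clopper-Pearson-type equal-tailed interval
  ``(F(X-1,.)^-1(1-g/2), F(X,.)^-1(g/2))`` — conservative by construction;
* Blaker: acceptability-function interval, conservative and a subset of CP;
* midQ: endpoints are the averages of the x and x-1 quantile inverses;
* midP: test inversion with the linearly interpolated distribution
  function ``(F(X-1, a) + F(X, a)) / 2``.

Counts at a support extreme get one-sided intervals whose informative
endpoint follows from each construction's own inversion: the CP constraint
on the missing tail is vacuous so its informative tail keeps gamma/2,
whereas the interpolated midP criterion reduces to ``F(kmin, a) > gamma``
and so (like midQ) spends the full budget in the informative tail, and
Blaker inverts its acceptability function directly.  The uninformative
endpoint is reported as the ``±log(2 N^2)`` surrogate.  All two-sided
endpoints are intersected with the working range ``(-cap, cap)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .distribution import (
    ALPHA_TOL,
    DEFAULT_CAP,
    DegenerateTableError,
    TableMargins,
    cdf,
    inverse_cdf_alpha,
    log_pmf_vector,
)
from .estimation import Table2x2, extreme_surrogate

#: Bisection tolerance for Blaker endpoint refinement.
BLAKER_TOL = 1e-6
#: Grid density of the Blaker endpoint scan inside the CP interval.
BLAKER_SCAN_POINTS = 400


@dataclass(frozen=True)
class AlphaInterval:
    """An open interval of affinity values.

    ``one_sided`` marks boundary-count intervals whose uninformative
    endpoint is the ``±log(2 N^2)`` surrogate standing in for ∓/±infinity;
    ``clipped`` marks endpoints truncated to the working range (-cap, cap).
    """

    lower: float
    upper: float
    kind: str
    one_sided: bool = False
    clipped: bool = False

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, alpha: float) -> bool:
        return self.lower <= alpha <= self.upper

    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class IntervalSet:
    """The median interval plus all four confidence intervals at one level."""

    median_interval: AlphaInterval
    ci_cp: AlphaInterval
    ci_blaker: AlphaInterval
    ci_midq: AlphaInterval
    ci_midp: AlphaInterval
    level: float

    def as_dict(self) -> dict[str, AlphaInterval]:
        return {
            "median": self.median_interval,
            "cp": self.ci_cp,
            "blaker": self.ci_blaker,
            "midq": self.ci_midq,
            "midp": self.ci_midp,
        }


def _check_level(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return 1.0 - level  # gamma


def _clip(lo: float, hi: float, cap: float, kind: str,
          one_sided: bool = False, pre_clipped: bool = False) -> AlphaInterval:
    clipped = pre_clipped
    if not one_sided:
        if lo < -cap:
            lo, clipped = -cap, True
        if hi > cap:
            hi, clipped = cap, True
    return AlphaInterval(lo, hi, kind, one_sided=one_sided, clipped=clipped)


def _one_sided(table: Table2x2, q_tail: float, kind: str,
               cap: float) -> AlphaInterval:
    """Interval for a count at a support extreme: the full tail budget
    ``q_tail`` goes into the single informative tail."""
    m = table.margins
    s = extreme_surrogate(m.N)
    if table.X == m.kmin:
        hi, clip = inverse_cdf_alpha(m.kmin, m, q_tail, cap)
        return AlphaInterval(-s, hi, kind, one_sided=True, clipped=clip)
    lo, clip = inverse_cdf_alpha(m.kmax - 1, m, 1.0 - q_tail, cap)
    return AlphaInterval(lo, s, kind, one_sided=True, clipped=clip)


def quantile_alpha_interval(
    x: int, margins: TableMargins, q: float, cap: float = DEFAULT_CAP
) -> AlphaInterval:
    """Open interval of alpha values for which ``x`` is a valid q-quantile
    of the co-occurrence distribution; with ``q = 1/2`` this is the median
    interval, whose width measures the discreteness of the distribution."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if margins.is_degenerate:
        raise DegenerateTableError("single-point support: no quantile interval")
    if x == margins.kmin or x == margins.kmax:
        return _one_sided(Table2x2(x, margins), q if x == margins.kmin else 1 - q,
                          "median" if q == 0.5 else "quantile", cap)
    lo, c1 = inverse_cdf_alpha(x - 1, margins, q, cap)
    hi, c2 = inverse_cdf_alpha(x, margins, q, cap)
    return _clip(lo, hi, cap, "median" if q == 0.5 else "quantile",
                 pre_clipped=c1 or c2)


def ci_cp(table: Table2x2, level: float = 0.95,
          cap: float = DEFAULT_CAP) -> AlphaInterval:
    """Clopper-Pearson-type equal-tailed exact confidence interval."""
    g = _check_level(level)
    m = table.margins
    if m.is_degenerate:
        raise DegenerateTableError("single-point support: no interval")
    if table.X in (m.kmin, m.kmax):
        # the constraint from the missing tail is vacuous, so the natural
        # inversion keeps gamma/2 in the informative tail
        return _one_sided(table, g / 2.0, "cp", cap)
    lo, c1 = inverse_cdf_alpha(table.X - 1, m, 1.0 - g / 2.0, cap)
    hi, c2 = inverse_cdf_alpha(table.X, m, g / 2.0, cap)
    return _clip(lo, hi, cap, "cp", pre_clipped=c1 or c2)


def ci_midq(table: Table2x2, level: float = 0.95,
            cap: float = DEFAULT_CAP) -> AlphaInterval:
    """midQ interval: each endpoint is the midpoint of the corresponding
    pair of quantile inverses at x and x-1 (interpolated quantiles)."""
    g = _check_level(level)
    m = table.margins
    if m.is_degenerate:
        raise DegenerateTableError("single-point support: no interval")
    if table.X in (m.kmin, m.kmax):
        return _one_sided(table, g, "midq", cap)
    x = table.X
    lo_a, c1 = inverse_cdf_alpha(x, m, 1.0 - g / 2.0, cap)
    lo_b, c2 = inverse_cdf_alpha(x - 1, m, 1.0 - g / 2.0, cap)
    hi_a, c3 = inverse_cdf_alpha(x, m, g / 2.0, cap)
    hi_b, c4 = inverse_cdf_alpha(x - 1, m, g / 2.0, cap)
    return _clip(0.5 * (lo_a + lo_b), 0.5 * (hi_a + hi_b), cap, "midq",
                 pre_clipped=c1 or c2 or c3 or c4)


def _interp_cdf(x: int, margins: TableMargins, alpha: float) -> float:
    """The linearly interpolated ("mid") distribution function
    (F(x-1, a) + F(x, a)) / 2, strictly decreasing in alpha."""
    return 0.5 * (cdf(x - 1, margins, alpha) + cdf(x, margins, alpha))


def ci_midp(table: Table2x2, level: float = 0.95,
            cap: float = DEFAULT_CAP) -> AlphaInterval:
    """midP interval: test inversion on the interpolated distribution
    function, i.e. ``{a : g/2 < (F(X-1,a)+F(X,a))/2 < 1-g/2}``."""
    g = _check_level(level)
    m = table.margins
    if m.is_degenerate:
        raise DegenerateTableError("single-point support: no interval")
    if table.X in (m.kmin, m.kmax):
        # (F(kmin-1, a) + F(kmin, a)) / 2 > g/2  reduces to  F(kmin, a) > g:
        # the interpolated criterion spends the full budget in one tail
        return _one_sided(table, g, "midp", cap)
    x = table.X

    def solve(r: float) -> tuple[float, bool]:
        f_lo = _interp_cdf(x, m, -cap)
        f_hi = _interp_cdf(x, m, cap)
        if f_lo < r:
            return -cap, True
        if f_hi > r:
            return cap, True
        a = brentq(lambda t: _interp_cdf(x, m, t) - r, -cap, cap,
                   xtol=ALPHA_TOL, maxiter=200)
        return float(a), False

    lo, c1 = solve(1.0 - g / 2.0)
    hi, c2 = solve(g / 2.0)
    return _clip(lo, hi, cap, "midp", pre_clipped=c1 or c2)


def blaker_acceptability(x: int, margins: TableMargins, alpha: float) -> float:
    """Blaker's acceptability: the smaller tail probability of the observed
    count plus the largest opposite-tail mass not exceeding it.  Ties
    (equal tails) score 1: the point is maximally compatible with the data."""
    lv = log_pmf_vector(margins, alpha)
    p = np.exp(lv)
    idx = x - margins.kmin
    lower = np.cumsum(p)                      # P(X <= k)
    upper = np.cumsum(p[::-1])[::-1]          # P(X >= k)
    q2 = float(lower[idx])                    # P(X <= x)
    q1 = float(upper[idx])                    # P(X >= x)
    tol = 1e-12
    if abs(q1 - q2) <= tol:
        return 1.0
    if q1 < q2:
        opp = lower[lower <= q1 + tol]
    else:
        opp = upper[upper <= q2 + tol]
        q1 = q2
    return q1 + (float(opp.max()) if opp.size else 0.0)


def _blaker_one_sided(table: Table2x2, g: float, cap: float) -> AlphaInterval:
    """Blaker interval for a boundary count: direct inversion of the
    acceptability criterion.  The informative endpoint lies between the
    full-gamma and half-gamma one-sided CP endpoints."""
    m = table.margins
    s = extreme_surrogate(m.N)
    x = table.X
    if x == m.kmin:
        a_in, _ = inverse_cdf_alpha(m.kmin, m, g, cap)       # acc >= g here
        a_out, _ = inverse_cdf_alpha(m.kmin, m, g / 2.0, cap)  # acc <= g beyond
    else:
        a_in, _ = inverse_cdf_alpha(m.kmax - 1, m, 1.0 - g, cap)
        a_out, _ = inverse_cdf_alpha(m.kmax - 1, m, 1.0 - g / 2.0, cap)
    endpoint = _outermost_crossing(x, m, g, a_in, a_out)
    if x == m.kmin:
        return AlphaInterval(-s, endpoint, "blaker", one_sided=True)
    return AlphaInterval(endpoint, s, "blaker", one_sided=True)


def _outermost_crossing(x: int, m: TableMargins, g: float,
                        a_in: float, a_out: float) -> float:
    """Locate sup/inf{a : acceptability(a) > g} between ``a_in`` (inside the
    acceptance region) and ``a_out`` (beyond it).

    The acceptability is a sawtooth in alpha — piecewise smooth with upward
    jumps where the opposite-tail argmax changes — so the region can dip
    below g and recover; a plain bisection may land on an inner crossing.
    Each pass subdivides the current bracket and keeps the outermost
    subinterval whose inner edge is still accepted, shrinking the bracket
    geometrically while never discarding a recovery window wider than the
    current resolution."""
    splits = 40
    while abs(a_out - a_in) > BLAKER_TOL:
        grid = np.linspace(a_in, a_out, splits)
        acc = [blaker_acceptability(x, m, a) for a in grid[1:-1]]
        inner = [i + 1 for i, v in enumerate(acc) if v > g]
        if inner:
            j = inner[-1]
            a_in, a_out = grid[j], grid[j + 1] if j + 1 < splits else a_out
        else:
            a_out = grid[1]
    return 0.5 * (a_in + a_out)


def ci_blaker(table: Table2x2, level: float = 0.95,
              cap: float = DEFAULT_CAP) -> AlphaInterval:
    """Blaker confidence interval ``{a0 : acceptability(a0, X) > gamma}``;
    conservative and a subset of the CP interval.  Endpoints are located by
    a dense scan over the CP interval followed by bisection refinement."""
    g = _check_level(level)
    m = table.margins
    if m.is_degenerate:
        raise DegenerateTableError("single-point support: no interval")
    if table.X in (m.kmin, m.kmax):
        return _blaker_one_sided(table, g, cap)
    cp = ci_cp(table, level, cap)
    x = table.X
    # acc = q2 + opp with q2 the observed-side tail and 0 <= opp <= q2, so
    # q2 <= acc <= 2 q2: each Blaker endpoint lies between the full-gamma
    # quantile inverse (acc surely > g inside it) and the CP endpoint
    # (q2 = g/2 there, acc surely <= g beyond).  Scan that narrow bracket.
    lo_in, _ = inverse_cdf_alpha(x - 1, m, 1.0 - g, cap)
    hi_in, _ = inverse_cdf_alpha(x, m, g, cap)

    def endpoint(a_in: float, a_out: float) -> float:
        if a_in == a_out:
            return a_in
        grid = np.linspace(a_in, a_out, BLAKER_SCAN_POINTS)
        acc = np.array([blaker_acceptability(x, m, a) for a in grid[1:-1]])
        inner = np.nonzero(acc > g)[0]
        if inner.size:
            j = inner[-1] + 1
            a_in, a_out = grid[j], grid[min(j + 1, len(grid) - 1)]
        else:
            a_out = grid[1]
        return _outermost_crossing(x, m, g, a_in, a_out)

    lo = endpoint(lo_in, cp.lower)
    hi = endpoint(hi_in, cp.upper)
    return AlphaInterval(float(lo), float(hi), "blaker", clipped=cp.clipped)


_CI_BUILDERS = {"cp": ci_cp, "blaker": ci_blaker, "midq": ci_midq, "midp": ci_midp}


def confidence_interval(table: Table2x2, ci_type: str, level: float = 0.95,
                        cap: float = DEFAULT_CAP) -> AlphaInterval:
    """Dispatch to one of the four interval constructions by name."""
    try:
        builder = _CI_BUILDERS[ci_type]
    except KeyError:
        raise ValueError(
            f"unknown interval type {ci_type!r}; expected one of "
            f"{sorted(_CI_BUILDERS)}"
        ) from None
    return builder(table, level, cap)


def interval_set(table: Table2x2, level: float = 0.95,
                 cap: float = DEFAULT_CAP) -> IntervalSet:
    """The median interval and all four confidence intervals for one table."""
    return IntervalSet(
        median_interval=quantile_alpha_interval(table.X, table.margins, 0.5, cap),
        ci_cp=ci_cp(table, level, cap),
        ci_blaker=ci_blaker(table, level, cap),
        ci_midq=ci_midq(table, level, cap),
        ci_midp=ci_midp(table, level, cap),
        level=level,
    )
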