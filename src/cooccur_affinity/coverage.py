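"""Exact true-coverage-probability curves for the affinity intervals.

For fixed margins and a chosen interval type, the true coverage at a
parameter value alpha is

    C(alpha) = sum_k  P(X = k; alpha) * 1{ alpha in CI(k) },

an exact enumeration over the support (no simulation).  The set of counts
covering a given alpha is piecewise constant in alpha, changing only at
interval endpoints ("breakpoints"), so the whole curve is characterised by
evaluating at every breakpoint plus one interior point per segment.

The summary fraction of evaluation points with coverage below the nominal
level is, by convention, computed over the breakpoints — the alpha values
where the coverage curve changes direction; the figure over all evaluation
points (breakpoints and segment midpoints) is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distribution import DEFAULT_CAP, TableMargins, pmf_vector
from .estimation import Table2x2
from .intervals import AlphaInterval, confidence_interval

#: Default alpha range over which coverage curves are traced.
DEFAULT_ALPHA_RANGE = (-4.0, 4.0)

#: Absolute slack on the inclusive (upper) side of interval membership.
#: Blaker endpoints of different counts share acceptability-jump locations
#: and are located numerically to ~1e-6; without this slack an evaluation
#: point on a shared jump can spuriously drop a count that the exact
#: construction accepts there.
MEMBERSHIP_ATOL = 5e-6


def intervals_for_all_counts(
    margins: TableMargins,
    ci_type: str,
    level: float = 0.95,
    cap: float = DEFAULT_CAP,
) -> list[AlphaInterval]:
    """The interval of the requested type for every count in the support,
    in support order.  Boundary counts get their one-sided form, with the
    uninformative side treated as unbounded for membership purposes."""
    out = []
    for k in range(margins.kmin, margins.kmax + 1):
        ci = confidence_interval(Table2x2(k, margins), ci_type, level, cap)
        if ci.one_sided:
            # the surrogate endpoint stands in for +-infinity; coverage
            # membership must treat that side as unbounded
            if k == margins.kmin:
                ci = AlphaInterval(-np.inf, ci.upper, ci.kind,
                                   one_sided=True, clipped=ci.clipped)
            else:
                ci = AlphaInterval(ci.lower, np.inf, ci.kind,
                                   one_sided=True, clipped=ci.clipped)
        out.append(ci)
    return out


def coverage_at(
    alpha: float,
    margins: TableMargins,
    ci_type: str | None = None,
    level: float = 0.95,
    cap: float = DEFAULT_CAP,
    intervals: list[AlphaInterval] | None = None,
) -> float:
    """Exact probability that the interval built from a count drawn at the
    true value ``alpha`` covers ``alpha``.

    Membership at an endpoint (a measure-zero convention) takes the curve's
    left limit: lower endpoints are exclusive, upper endpoints inclusive.
    Pass precomputed ``intervals`` to avoid rebuilding them when evaluating
    many alphas."""
    if intervals is None:
        if ci_type is None:
            raise ValueError("either ci_type or intervals must be given")
        intervals = intervals_for_all_counts(margins, ci_type, level, cap)
    p = pmf_vector(margins, alpha)
    member = np.array(
        [ci.lower < alpha <= ci.upper + MEMBERSHIP_ATOL for ci in intervals]
    )
    return float(p[member].sum())


@dataclass(frozen=True)
class CoverageCurve:
    """Exact coverage curve of one interval type over an alpha range.

    ``alphas``/``values`` hold every evaluation point (breakpoints plus one
    midpoint per inter-breakpoint segment) in increasing alpha order;
    ``is_breakpoint`` marks which of them are curve breakpoints.
    """

    margins: TableMargins
    ci_type: str
    level: float
    alpha_range: tuple[float, float]
    breakpoints: np.ndarray
    alphas: np.ndarray
    values: np.ndarray
    is_breakpoint: np.ndarray
    intervals: list[AlphaInterval] = field(repr=False)

    @property
    def breakpoint_values(self) -> np.ndarray:
        return self.values[self.is_breakpoint]


def coverage_curve(
    margins: TableMargins,
    ci_type: str,
    level: float = 0.95,
    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE,
    cap: float = DEFAULT_CAP,
) -> CoverageCurve:
    """Trace the exact coverage curve of one interval type.

    Breakpoints are the interval endpoints (over all counts in the support)
    falling inside ``alpha_range``, plus the range limits; the coverage is
    evaluated at every breakpoint and at every segment midpoint.
    """
    lo, hi = alpha_range
    if lo >= hi:
        raise ValueError(f"alpha_range must be increasing, got {alpha_range}")
    intervals = intervals_for_all_counts(margins, ci_type, level, cap)
    ends = np.array(
        [e for ci in intervals for e in (ci.lower, ci.upper) if lo < e < hi]
    )
    breakpoints = np.unique(np.concatenate([[lo], ends, [hi]]))
    mids = 0.5 * (breakpoints[:-1] + breakpoints[1:])
    alphas = np.concatenate([breakpoints, mids])
    flags = np.concatenate(
        [np.ones(len(breakpoints), bool), np.zeros(len(mids), bool)]
    )
    order = np.argsort(alphas, kind="stable")
    alphas, flags = alphas[order], flags[order]
    values = np.array(
        [coverage_at(a, margins, intervals=intervals) for a in alphas]
    )
    return CoverageCurve(
        margins=margins,
        ci_type=ci_type,
        level=level,
        alpha_range=(float(lo), float(hi)),
        breakpoints=breakpoints,
        alphas=alphas,
        values=values,
        is_breakpoint=flags,
        intervals=intervals,
    )


@dataclass(frozen=True)
class CoverageSummary:
    """Summary statistics of a coverage curve against its nominal level.

    ``fraction_below_nominal`` is computed over every evaluation point
    (breakpoints plus segment midpoints — the set that characterises the
    whole curve); ``fraction_below_nominal_breakpoints`` restricts to the
    breakpoints alone.
    """

    ci_type: str
    level: float
    min_coverage: float
    max_coverage: float
    fraction_below_nominal: float
    fraction_below_nominal_breakpoints: float
    max_undercoverage: float
    max_overcoverage: float


def coverage_summary(curve: CoverageCurve) -> CoverageSummary:
    v_all = curve.values
    v_bp = curve.breakpoint_values
    level = curve.level
    return CoverageSummary(
        ci_type=curve.ci_type,
        level=level,
        min_coverage=float(v_all.min()),
        max_coverage=float(v_all.max()),
        fraction_below_nominal=float(np.mean(v_all < level)),
        fraction_below_nominal_breakpoints=float(np.mean(v_bp < level)),
        max_undercoverage=float(max(0.0, level - v_all.min())),
        max_overcoverage=float(max(0.0, v_all.max() - level)),
    )
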