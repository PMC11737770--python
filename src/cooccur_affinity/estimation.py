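"""Conditional MLE of the affinity parameter and classical similarity indices.

The affinity alpha is the log odds ratio of a 2x2 occurrence table with
both margins fixed.  Its conditional MLE maximises the Extended
Hypergeometric likelihood in alpha; by exponential-family stationarity this
is equivalent to solving the mean equation ``E[X; alpha] = X``, which is
monotone in alpha and solved here by bracketed root finding.

Counts at the support extremes are compatible with alpha = -inf / +inf; the
estimate is then replaced by the finite Bayesian-motivated surrogate
``-log(2 N^2)`` / ``+log(2 N^2)`` and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import hypergeom

from .distribution import (
    ALPHA_TOL,
    DEFAULT_CAP,
    DegenerateTableError,
    TableMargins,
    log_pmf,
    mean,
)


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 occurrence table: co-occurrence count ``X`` plus fixed margins."""

    X: int
    margins: TableMargins

    def __post_init__(self) -> None:
        if not float(self.X).is_integer():
            raise ValueError(f"X must be an integer, got {self.X!r}")
        object.__setattr__(self, "X", int(self.X))
        m = self.margins
        if not m.kmin <= self.X <= m.kmax:
            raise ValueError(
                f"X={self.X} outside the support [{m.kmin}, {m.kmax}] implied "
                f"by margins (mA={m.mA}, mB={m.mB}, N={m.N})"
            )

    @classmethod
    def from_counts(cls, X: int, mA: int, mB: int, N: int) -> "Table2x2":
        return cls(X, TableMargins(mA, mB, N))

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(both, A only, B only, neither)."""
        m = self.margins
        return (self.X, m.mA - self.X, m.mB - self.X, m.N - m.mA - m.mB + self.X)


def extreme_surrogate(N: int) -> float:
    """log(2 N^2): the finite stand-in for an infinite boundary MLE."""
    return math.log(2.0 * N * N)


@dataclass(frozen=True)
class AlphaEstimate:
    """Conditional MLE of alpha with its log-likelihood and boundary flags."""

    estimate: float
    log_likelihood: float
    is_extreme_low: bool = False
    is_extreme_high: bool = False
    is_capped: bool = False

    @property
    def is_extreme(self) -> bool:
        return self.is_extreme_low or self.is_extreme_high


def ml_alpha(table: Table2x2, cap: float = DEFAULT_CAP) -> AlphaEstimate:
    """Conditional maximum-likelihood estimate of the affinity alpha.

    For interior ``X`` solves ``E[X; alpha] = X`` by monotone root finding,
    clipping the result to ``[-cap, cap]`` (``is_capped`` set if clipping
    occurred).  For ``X`` at a support extreme returns the surrogate
    ``±log(2 N^2)`` with the matching extremity flag.

    Raises
    ------
    DegenerateTableError
        When ``mA`` or ``mB`` is 0 or N (single-point support).
    """
    m = table.margins
    if m.is_degenerate:
        raise DegenerateTableError(
            f"margins (mA={m.mA}, mB={m.mB}, N={m.N}) give single-point "
            f"support; alpha is not estimable"
        )
    X = table.X
    if X == m.kmax:
        a = extreme_surrogate(m.N)
        return AlphaEstimate(a, log_pmf(X, m, a), is_extreme_high=True)
    if X == m.kmin:
        a = -extreme_surrogate(m.N)
        return AlphaEstimate(a, log_pmf(X, m, a), is_extreme_low=True)

    g = lambda a: mean(m, a) - X
    if g(-cap) >= 0.0:  # uncapped root below -cap
        return AlphaEstimate(-cap, log_pmf(X, m, -cap), is_capped=True)
    if g(cap) <= 0.0:
        return AlphaEstimate(cap, log_pmf(X, m, cap), is_capped=True)
    a = brentq(g, -cap, cap, xtol=ALPHA_TOL, maxiter=200)
    return AlphaEstimate(float(a), log_pmf(X, m, a))


@dataclass(frozen=True)
class NullSummary:
    """Null-model (alpha = 0) expectation and two-sided exact p-value."""

    expected_cooccurrence: float
    p_value: float


def null_summary(table: Table2x2) -> NullSummary:
    """Expected co-occurrence mA*mB/N and a two-sided central-hypergeometric
    p-value (doubled smaller tail, capped at 1)."""
    m = table.margins
    expected = m.mA * m.mB / m.N
    dist = hypergeom(m.N, m.mA, m.mB)
    lower = dist.cdf(table.X)
    upper = dist.sf(table.X - 1)
    p = min(1.0, 2.0 * min(lower, upper))
    return NullSummary(expected, float(p))


@dataclass(frozen=True)
class TraditionalIndices:
    """Jaccard, Sorensen-Dice and Simpson similarities (NaN where the
    defining denominator vanishes)."""

    jaccard: float
    sorensen_dice: float
    simpson: float


def traditional_indices(table: Table2x2) -> TraditionalIndices:
    """Classical co-occurrence similarity indices for the same table.

    jaccard = X / (mA + mB - X); sorensen_dice = 2 X / (mA + mB);
    simpson = X / min(mA, mB).  Undefined ratios (0/0) are returned as NaN
    rather than raising.
    """
    m = table.margins
    X = table.X
    union = m.mA + m.mB - X
    jaccard = X / union if union > 0 else math.nan
    sorensen = 2 * X / (m.mA + m.mB) if (m.mA + m.mB) > 0 else math.nan
    smaller = min(m.mA, m.mB)
    simpson = X / smaller if smaller > 0 else math.nan
    return TraditionalIndices(jaccard, sorensen, simpson)
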