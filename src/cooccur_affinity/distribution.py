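"""Extended (Fisher noncentral) hypergeometric distribution for 2x2 tables.

The co-occurrence count ``X`` of two entities with fixed occurrence totals
``mA``, ``mB`` out of ``N`` elements follows the Extended Hypergeometric
distribution with log odds-ratio parameter ``alpha``:

    P(X = k) ∝ C(mA, k) * C(N - mA, mB - k) * exp(k * alpha)

on the support ``max(mA + mB - N, 0) <= k <= min(mA, mB)``.  At
``alpha = 0`` this is the central hypergeometric null model of random
placement.  Everything here is computed by explicit enumeration of the
support in log space (log-gamma binomial coefficients, log-sum-exp
normalisation), which is exact and stable for margins up to ``N ~ 1e5``
and ``|alpha| <= ~30``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

#: Default working cap on |alpha| for root searches and interval clipping.
DEFAULT_CAP = 10.0

#: Convergence tolerance (in alpha) for all monotone root searches.
ALPHA_TOL = 1e-8


class DegenerateTableError(ValueError):
    """Raised when the support is a single point (mA or mB in {0, N}) and
    the requested operation (inversion, estimation) is undefined."""


@dataclass(frozen=True)
class TableMargins:
    """Fixed margins of a 2x2 occurrence table.

    Attributes
    ----------
    mA, mB : int
        Number of elements (e.g. sites) occupied by entity A and B.
    N : int
        Total number of elements.
    kmin, kmax : int
        Derived support bounds of the co-occurrence count,
        ``kmin = max(mA + mB - N, 0)``, ``kmax = min(mA, mB)``.
    """

    mA: int
    mB: int
    N: int
    kmin: int = field(init=False)
    kmax: int = field(init=False)

    def __post_init__(self) -> None:
        for name in ("mA", "mB", "N"):
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        for name in ("mA", "mB"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            if v > self.N:
                raise ValueError(f"{name} must be <= N={self.N}, got {v}")
        object.__setattr__(self, "kmin", max(self.mA + self.mB - self.N, 0))
        object.__setattr__(self, "kmax", min(self.mA, self.mB))

    @property
    def is_degenerate(self) -> bool:
        """True when the support is a single point."""
        return self.kmin == self.kmax

    def swapped(self) -> "TableMargins":
        return TableMargins(self.mB, self.mA, self.N)


def support_bounds(margins: TableMargins) -> tuple[int, int]:
    """Return ``(kmin, kmax)``, the logically possible co-occurrence counts."""
    return margins.kmin, margins.kmax


def _log_weights(margins: TableMargins, alpha: float) -> np.ndarray:
    """Unnormalised log weights log C(mA,k) + log C(N-mA, mB-k) + k*alpha
    over the whole support."""
    k = np.arange(margins.kmin, margins.kmax + 1)
    mA, mB, N = margins.mA, margins.mB, margins.N
    lw = (
        gammaln(mA + 1) - gammaln(k + 1) - gammaln(mA - k + 1)
        + gammaln(N - mA + 1) - gammaln(mB - k + 1) - gammaln(N - mA - mB + k + 1)
        + k * float(alpha)
    )
    return lw


def log_pmf_vector(margins: TableMargins, alpha: float) -> np.ndarray:
    """Normalised log pmf over the full support ``kmin..kmax``."""
    lw = _log_weights(margins, alpha)
    return lw - logsumexp(lw)


def pmf_vector(margins: TableMargins, alpha: float) -> np.ndarray:
    return np.exp(log_pmf_vector(margins, alpha))


def log_pmf(k: int, margins: TableMargins, alpha: float) -> float:
    """Log probability of co-occurrence count ``k``; -inf off the support."""
    if k < margins.kmin or k > margins.kmax:
        logger.debug(
            "log_pmf: k=%d outside support [%d, %d]", k, margins.kmin, margins.kmax
        )
        return -np.inf
    return float(log_pmf_vector(margins, alpha)[k - margins.kmin])


def cdf(x: int, margins: TableMargins, alpha: float) -> float:
    """F(x, alpha) = P(X <= x); strictly decreasing in alpha for interior x."""
    x = int(np.floor(x))
    if x < margins.kmin:
        return 0.0
    if x >= margins.kmax:
        return 1.0
    lv = log_pmf_vector(margins, alpha)
    return float(min(1.0, np.exp(logsumexp(lv[: x - margins.kmin + 1]))))


def sf(x: int, margins: TableMargins, alpha: float) -> float:
    """P(X >= x), computed from the upper-tail log-sum for accuracy."""
    x = int(np.ceil(x))
    if x <= margins.kmin:
        return 1.0
    if x > margins.kmax:
        return 0.0
    lv = log_pmf_vector(margins, alpha)
    return float(min(1.0, np.exp(logsumexp(lv[x - margins.kmin:]))))


def inverse_cdf_alpha(
    x: int,
    margins: TableMargins,
    r: float,
    cap: float = DEFAULT_CAP,
) -> tuple[float, bool]:
    """Solve ``F(x, a) = r`` for the log odds ratio ``a``.

    F(x, .) is strictly decreasing from 1 to 0 for interior ``x``, so the
    root is unique.  The search bracket is ``[-cap, cap]``; when the root
    lies outside, the nearer bracket end is returned with ``clipped=True``.

    Returns
    -------
    (alpha, clipped)

    Raises
    ------
    DegenerateTableError
        If the support is a single point.
    ValueError
        If ``x`` is outside ``[kmin, kmax - 1]`` (F is then identically 0
        or 1 and has no inverse; callers should apply the extreme-endpoint
        substitution policy instead) or ``r`` not in (0, 1).
    """
    if margins.is_degenerate:
        raise DegenerateTableError(
            f"support is the single point {margins.kmin}; no inverse exists"
        )
    if not 0.0 < r < 1.0:
        raise ValueError(f"r must be in (0, 1), got {r}")
    if x < margins.kmin or x >= margins.kmax:
        raise ValueError(
            f"F(x, .) is constant for x={x} outside [{margins.kmin}, "
            f"{margins.kmax - 1}]; use the extreme-endpoint substitution policy"
        )
    f_lo = cdf(x, margins, -cap)  # close to 1
    f_hi = cdf(x, margins, cap)   # close to 0
    if f_lo < r:  # root below -cap
        logger.debug("inverse_cdf_alpha clipped at -%g (F=%g < r=%g)", cap, f_lo, r)
        return -cap, True
    if f_hi > r:  # root above +cap
        logger.debug("inverse_cdf_alpha clipped at +%g (F=%g > r=%g)", cap, f_hi, r)
        return cap, True
    a = brentq(lambda t: cdf(x, margins, t) - r, -cap, cap,
               xtol=ALPHA_TOL, maxiter=200)
    return float(a), False


def mean(margins: TableMargins, alpha: float) -> float:
    """E[X; alpha] by enumeration; strictly increasing in alpha."""
    k = np.arange(margins.kmin, margins.kmax + 1)
    return float(np.sum(k * pmf_vector(margins, alpha)))


def sample(
    margins: TableMargins,
    alpha: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. co-occurrence counts by inverse-CDF lookup on the
    enumerated pmf.  ``rng`` may be a Generator or a seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    k = np.arange(margins.kmin, margins.kmax + 1)
    p = pmf_vector(margins, alpha)
    p = p / p.sum()
    cum = np.cumsum(p)
    u = rng.random(n)
    return k[np.searchsorted(cum, u, side="right").clip(0, len(k) - 1)]
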