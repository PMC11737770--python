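"""Distribution core vs independent oracles (scipy, brute-force enumeration)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import gammaln

from cooccur_affinity import (
    TableMargins,
    cdf,
    inverse_cdf_alpha,
    log_pmf,
    log_pmf_vector,
    mean,
    pmf_vector,
    sample,
    support_bounds,
)
from cooccur_affinity.distribution import DegenerateTableError


def brute_pmf(m: TableMargins, alpha: float) -> np.ndarray:
    """Independent enumeration of the noncentral hypergeometric pmf,
    deliberately written differently from the library (direct ratio of
    exponentiated log terms, no log-sum-exp)."""
    ks = np.arange(m.kmin, m.kmax + 1)
    logw = (
        gammaln(m.mA + 1) - gammaln(ks + 1) - gammaln(m.mA - ks + 1)
        + gammaln(m.N - m.mA + 1) - gammaln(m.mB - ks + 1)
        - gammaln(m.N - m.mA - m.mB + ks + 1)
    )
    w = np.exp(logw - logw.max()) * np.exp(
        (ks - ks.mean()) * alpha
    )  # centered to avoid overflow
    return w / w.sum()


@pytest.mark.parametrize(
    "mA,mB,N,expected",
    [(50, 70, 150, (0, 50)), (100, 120, 150, (70, 100)), (0, 70, 150, (0, 0))],
)
def test_support_bounds(mA, mB, N, expected):
    assert support_bounds(TableMargins(mA, mB, N)) == expected


@pytest.mark.parametrize(
    "bad", [{"mA": -1, "mB": 5, "N": 10}, {"mA": 5, "mB": 11, "N": 10},
            {"mA": 0, "mB": 0, "N": 0}]
)
def test_invalid_margins_name_the_offending_field(bad):
    with pytest.raises(ValueError):
        TableMargins(**bad)


@pytest.mark.parametrize("alpha", [-10.0, -3.0, 0.0, 3.0, 10.0])
def test_pmf_normalises_and_matches_enumeration(small_margin_sets, alpha):
    for m in small_margin_sets:
        p = pmf_vector(m, alpha)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p, brute_pmf(m, alpha), atol=1e-12)


def test_central_case_is_hypergeometric(margins_main):
    """At alpha=0 pmf/cdf must agree with scipy's central hypergeometric."""
    m = margins_main
    hg = stats.hypergeom(m.N, m.mA, m.mB)
    ks = np.arange(m.kmin, m.kmax + 1)
    np.testing.assert_allclose(pmf_vector(m, 0.0), hg.pmf(ks), atol=1e-12)
    for x in ks:
        assert abs(cdf(int(x), m, 0.0) - hg.cdf(x)) < 1e-12


@pytest.mark.parametrize("alpha", [-2.5, -1.0, 0.7, 3.0])
def test_pmf_matches_scipy_noncentral(margins_main, alpha):
    """Cross-check against scipy's Fisher noncentral hypergeometric."""
    m = margins_main
    d = stats.nchypergeom_fisher(m.N, m.mA, m.mB, np.exp(alpha))
    ks = np.arange(m.kmin, m.kmax + 1)
    np.testing.assert_allclose(pmf_vector(m, alpha), d.pmf(ks), rtol=1e-9)


def test_symmetry_in_roles_of_A_and_B(small_margin_sets):
    for m in small_margin_sets:
        for alpha in (-2.0, 0.5, 4.0):
            np.testing.assert_allclose(
                log_pmf_vector(m, alpha),
                log_pmf_vector(m.swapped(), alpha),
                atol=1e-12,
            )


def test_log_pmf_off_support_is_minus_inf(margins_main):
    assert log_pmf(-1, margins_main, 0.3) == -np.inf
    assert log_pmf(51, margins_main, 0.3) == -np.inf


def test_large_margins_do_not_overflow():
    m = TableMargins(40_000, 55_000, 100_000)
    p = pmf_vector(m, 5.0)
    assert np.isfinite(p).all()
    assert abs(p.sum() - 1.0) < 1e-9


def test_cdf_matches_partial_sums_and_limits(margins_main):
    m = margins_main
    p = brute_pmf(m, 0.0)
    for x in range(m.kmin, m.kmax + 1):
        assert abs(cdf(x, m, 0.0) - p[: x - m.kmin + 1].sum()) < 1e-12
    assert cdf(m.kmin - 1, m, 2.0) == 0.0
    assert cdf(m.kmax, m, -7.0) == 1.0


def test_cdf_strictly_decreasing_in_alpha(margins_main):
    grid = np.linspace(-3.0, 3.3, 40)
    vals = [cdf(20, margins_main, a) for a in grid]
    assert all(b < a for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("r", [0.025, 0.5, 0.975])
def test_inverse_cdf_round_trip(margins_main, r):
    a, clipped = inverse_cdf_alpha(20, margins_main, r)
    assert not clipped
    assert abs(cdf(20, margins_main, a) - r) < 1e-7


def test_inverse_cdf_at_known_point_and_ordering(margins_main):
    r0 = cdf(20, margins_main, 0.0)
    a, _ = inverse_cdf_alpha(20, margins_main, r0)
    assert abs(a) < 1e-7
    hi, _ = inverse_cdf_alpha(20, margins_main, 0.025)
    lo, _ = inverse_cdf_alpha(20, margins_main, 0.975)
    assert lo < hi  # larger r -> smaller alpha


def test_inverse_cdf_rejects_extremes_and_degenerate(margins_main):
    with pytest.raises(ValueError, match="extreme-endpoint"):
        inverse_cdf_alpha(50, margins_main, 0.5)
    with pytest.raises(DegenerateTableError):
        inverse_cdf_alpha(0, TableMargins(0, 70, 150), 0.5)


def test_mean_matches_enumeration_and_is_increasing(margins_main):
    m = margins_main
    p = brute_pmf(m, 0.0)
    ks = np.arange(m.kmin, m.kmax + 1)
    assert abs(mean(m, 0.0) - float((ks * p).sum())) < 1e-10
    grid = np.linspace(-5, 5, 30)
    means = [mean(m, a) for a in grid]
    assert all(b > a for a, b in zip(means, means[1:]))
    assert mean(m, 10.0) > m.kmax - 0.1  # mass concentrates at kmax


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    mA=st.integers(0, 60),
    mB=st.integers(0, 60),
    N=st.integers(1, 60),
    alpha=st.floats(-8, 8, allow_nan=False),
)
def test_distribution_invariants_hold_for_arbitrary_margins(mA, mB, N, alpha):
    """Support bounds, normalisation, symmetry and mean-monotonicity hold
    for any valid margins and affinity."""
    if mA > N or mB > N:
        with pytest.raises(ValueError):
            TableMargins(mA, mB, N)
        return
    m = TableMargins(mA, mB, N)
    assert max(mA + mB - N, 0) == m.kmin <= m.kmax == min(mA, mB)
    p = pmf_vector(m, alpha)
    assert abs(p.sum() - 1.0) < 1e-10
    assert (p >= 0).all()
    np.testing.assert_allclose(p, pmf_vector(m.swapped(), alpha), atol=1e-12)
    if not m.is_degenerate:
        assert mean(m, alpha) < mean(m, alpha + 0.5)


def test_sampling_reproducible_and_in_support(margins_main):
    x1 = sample(margins_main, 1.0, 500, rng=7)
    x2 = sample(margins_main, 1.0, 500, rng=7)
    np.testing.assert_array_equal(x1, x2)
    assert x1.min() >= 0 and x1.max() <= 50


def test_sampling_matches_exact_pmf(margins_main):
    n = 100_000
    draws = sample(margins_main, 1.0, n, rng=123)
    p = pmf_vector(margins_main, 1.0)
    counts = np.bincount(draws, minlength=51)
    se = np.sqrt(n * p * (1 - p))
    # 3-standard-error band per cell, only where expected count is not tiny
    mask = n * p > 5
    assert (np.abs(counts[mask] - n * p[mask]) < 3.5 * se[mask]).all()
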