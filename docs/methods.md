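# Methods

## Model and estimand

For two entities with fixed occurrence totals `mA`, `mB` out of `N`
elements, the co-occurrence count `X` conditional on both totals follows
the Extended (Fisher noncentral) Hypergeometric distribution with a single
log odds-ratio parameter α (the *affinity*): `P(X=k) ∝ C(mA,k)·C(N−mA,
mB−k)·e^{kα}` on `kmin = max(mA+mB−N, 0) ≤ k ≤ kmax = min(mA, mB)`. The
distribution is symmetric in the roles of A and B, reduces to the central
hypergeometric at α = 0, and has the monotone-likelihood-ratio property,
so its CDF `F(x, α)` is strictly decreasing in α for interior `x` and its
mean is strictly increasing in α. Only α is estimated; the underlying
occupancy probabilities (p1, p2) enter only through α and reappear only in
the synthetic-data generator.

All probability computation enumerates the support in log space
(log-gamma binomial coefficients, log-sum-exp normalisation). This is
exact up to floating point, overflow-free for margins up to N ≈ 1e5, and
is also the test oracle: the suite cross-checks it against scipy's
`hypergeom` (α = 0, agreement 1e-12) and `nchypergeom_fisher` (general α),
which are never used in the computation path itself.

## Estimation

The conditional MLE solves the exponential-family score equation
`E[X; α] = X` by bracketed monotone root finding (`brentq`, tolerance
1e-8 in α, 200 iterations max — printed results carry 6 decimals).
Working range: the estimate is clipped to `[−M, M]` with `M = 10` by
default and flagged `is_capped`; M is a policy default for comparability
of outputs, not a numerical necessity of this implementation.

Boundary counts (`X = kmin` or `kmax`) are compatible with α = ∓∞; they
are reported as the Bayesian-motivated finite surrogate `∓log(2N²)` with
an extremity flag, and this surrogate is used even where `log(2N²) > M`
(the boundary value and the working cap serve different purposes and are
deliberately not reconciled). Tables with `mA` or `mB` in `{0, N}` have
single-point support; estimation and interval construction raise a typed
degenerate-table signal, which the matrix pipeline converts to missing
values with a reason code rather than dropping the pair.

The two-sided null p-value is the doubled smaller central-hypergeometric
tail, capped at 1 — the most common convention; the doubling-vs-summing
choice is not pinned down by any printed value we reproduce.

## Intervals

All intervals invert tests based on `F(x, α)`; endpoints solve
`F(x, α) = r` by the same monotone root finder, with the search bracket
`[−M, M]` and a `clipped` flag when the root lies outside. For a
significance budget γ (level 1−γ, default 0.95):

- **Quantile/median interval** `(F(x−1,·)⁻¹(q), F(x,·)⁻¹(q))`: the α
  values for which `x` is a valid q-quantile; adjacent counts share
  endpoints. We assert empirically (it is not proved) that the median
  interval contains the MLE; the suite checks this across several margin
  sets.
- **CP** `(F(X−1,·)⁻¹(1−γ/2), F(X,·)⁻¹(γ/2))` — conservative by
  construction.
- **midQ**: endpoints are midpoints of the x/x−1 quantile-inverse pairs.
- **midP**: inversion of the interpolated CDF `(F(X−1,α)+F(X,α))/2`,
  which is again strictly decreasing, so endpoints come from the same
  root finder.
- **Blaker**: `{α : acceptability(α, X) > γ}` with acceptability = the
  smaller tail plus the largest opposite-tail mass not exceeding it (1 on
  ties — the point is maximally compatible with the data). The
  acceptability is a sawtooth in α: smooth decay toward the tails with
  downward jumps where the opposite-tail argmax changes, and it typically
  *jumps across* γ rather than crossing it continuously. Endpoints are
  therefore searched in the tight bracket between the full-γ quantile
  inverse and the CP endpoint — valid because the observed-side tail q
  satisfies `q ≤ acceptability ≤ 2q` — by a 400-point scan plus an
  iterative outermost-crossing refinement to 1e-6 that cannot discard a
  recovery window wider than its current resolution. A plain bisection
  demonstrably finds inner crossings and breaks the interval's exact
  conservatism.

**Boundary counts** get one-sided intervals whose finite endpoint follows
from each construction's own inversion: for CP the constraint from the
missing tail is vacuous, so the informative tail keeps γ/2; for midP the
interpolated criterion reduces algebraically to `F(kmin, α) > γ` — the
full budget in one tail — and midQ follows midP; Blaker inverts its
acceptability directly (its endpoint lies between the two). The
uninformative endpoint is reported as `∓log(2N²)`. A uniform full-γ rule
was tried and rejected: it destroys the exact conservatism of CP
(minimum coverage drops to 0.9403 on the (50,70,150) reference margins),
while the per-type natural forms preserve it (0.9504) and keep Blaker
exactly conservative. Endpoints are open conceptually; see the coverage
conventions below for how measure-zero boundary cases are evaluated.

## Exact coverage

True coverage at α is `Σ_k P(X=k; α)·1{α ∈ CI(k)}`, enumerated exactly.
The covering-count set is piecewise constant between interval endpoints
("breakpoints"), so the curve is characterised by evaluating at every
breakpoint and every segment midpoint; for the (50,70,150) reference
margins this gives 181 evaluation points for CP/midQ/midP and 183 for
Blaker over the default range α ∈ (−4, 4).

Conventions, fixed once and used everywhere:

- Membership at an endpoint takes the curve's **left limit**: lower
  endpoints exclusive, upper inclusive (measure-zero choice).
- The inclusive side carries a 5e-6 absolute slack because Blaker
  endpoints of different counts coincide at shared acceptability jumps
  and are located to ~1e-6; without it an evaluation point on a shared
  jump spuriously drops a count the exact construction accepts.
- One-sided boundary intervals are unbounded on the uninformative side
  for membership purposes (the `log(2N²)` surrogate is a reporting
  device).
- `fraction_below_nominal` is taken over all evaluation points;
  the breakpoint-only figure is also reported.

With these conventions, on (50,70,150) at the 95% level the minimum exact
coverage of CP is 0.9504 and of Blaker 0.9500 (conservatism holds
exactly; the 1e-8-scale deficit at Blaker breakpoints is endpoint
round-off), the below-nominal fractions are 53.0% (midQ) and 43.6% (midP)
— these are the numbers `scripts/acceptance.py` recomputes. The exact
curves of the midQ/midP constructions dip to 0.902/0.928 in narrow α
windows adjacent to interval endpoints of low-probability boundary-near
counts, and the Blaker curve peaks at 0.986: pointwise deviations are
larger than the "few percent" a histogram of these curves visually
suggests. These dips were verified against a fully independent
scipy-only reconstruction of the intervals and coverage (agreement to
1e-12); they are properties of the constructions, not numerics.

## Synthetic data

The generator emulates the urn mechanism: entity A occupies `mA` of `N`
elements uniformly; B occupies A-elements with probability p1 and others
with p2, conditioned on its total `mB`. Because the conditional law of
the co-occurrence count is exactly the Extended Hypergeometric, the fast
samplers draw the count directly from the enumerated pmf (inverse-CDF
lookup, seeded `numpy` Generator); the site-by-site mechanism with
rejection on B's total is retained as a slow validation path and the two
are checked distributionally against each other in the suite. Matrix
generation conditions on all entity prevalences exactly (row sums are
deterministic); pairwise affinity can be injected for disjoint pairs
only, since higher-order dependence is outside the model. What the
generator does *not* emulate: spatial or phylogenetic autocorrelation,
site heterogeneity, covariate-driven prevalences, detection error —
passing recovery tests therefore says nothing about robustness to those
features of real data.

Default study conditions used by the recovery tests: margins
(500, 700, 1500) with true α ∈ {−2, 0, 2} and 2000 replicates for
2×2 recovery (mean α̂ within 0.1 of truth; empirical 95% midP coverage in
[0.93, 0.97]), and N = 200 with prevalences 80/90 for matrix-level
recovery — sizes chosen as representative moderate-sized surveys where
the MLE's small-sample bias is visible but modest.

## Known limitations

- Coverage evaluation points characterise the piecewise curve but the
  deepest point of a dip window need not be attained exactly at a
  breakpoint or midpoint; reported maxima/minima are accurate to the
  segment resolution.
- The Blaker acceptance region is treated as an interval (its measure of
  non-intervalness at sliver scale is absorbed by the outermost-crossing
  search and membership slack).
- No multiplicity adjustment across pairs in the matrix pipeline; raw
  per-pair p-values and intervals are reported.
- Abundance thresholding is a hard cut; no uncertainty from the
  binarisation step is propagated.
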