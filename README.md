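# cooccur-affinity

Affinity analysis of binary co-occurrence data: conditional
maximum-likelihood estimation of the log odds-ratio affinity parameter α
of a 2×2 occurrence table under the Extended (Fisher noncentral)
Hypergeometric model, with exact median and confidence intervals, exact
coverage diagnostics, and an end-to-end presence–absence matrix pipeline.

## Who this is for

Ecologists, biogeographers and epidemiologists who summarise pairwise
association from presence–absence data (species × sites, traits ×
patients, …). Traditional similarity indices (Jaccard, Sørensen–Dice,
Simpson) depend sensitively on prevalence and have no defined target of
estimation away from the null; the affinity α is a single interpretable
parameter that does not.

## The model

Two entities A and B occupy `mA` and `mB` of `N` elements. Conditional on
both totals, the co-occurrence count `X` follows the Extended
Hypergeometric distribution on `max(mA+mB−N, 0) ≤ k ≤ min(mA, mB)`:

    P(X = k) ∝ C(mA, k) · C(N−mA, mB−k) · e^{kα}

where `α = log[p1(1−p2)/(p2(1−p1))]` is the log odds ratio of B occupying
an A-occupied versus A-free element; `α = 0` recovers the central
hypergeometric null of random placement. The package provides:

- **MLE** `α̂`: the root of the monotone mean equation `E[X; α] = X`
  (exponential-family stationarity). Counts at a support extreme map to
  the finite surrogate `±log(2N²)` and are flagged.
- **Median interval**: all α for which the observed count is a valid
  median — its width measures the discreteness of the distribution.
- **Four exact confidence intervals** by test inversion on the CDF
  `F(x, α)` (strictly decreasing in α): Clopper–Pearson-type (CP),
  Blaker (acceptability inversion; conservative subset of CP), and the
  near-nominal midQ (averaged quantile inverses) and midP (interpolated
  CDF) intervals.
- **Exact coverage curves**: `C(α) = Σ_k P(X=k; α)·1{α ∈ CI(k)}` by
  enumeration — no simulation — with summaries of under/over-coverage.
- **Matrix pipeline**: validation/thresholding of presence–absence or
  abundance matrices, all pairwise 2×2 analyses along rows or columns,
  long-format and square-matrix output, heatmaps.
- **Synthetic data** under the urn model for calibration experiments.

## Worked example

The running example: `X = 35` co-occurrences with `mA = 50`, `mB = 70`,
`N = 150`.

```bash
cooccur-affinity table 35 50 70 150
```

```
alpha MLE:        1.455814
log-likelihood:   -1.912295
null expectation: 23.333333
null p-value:     0.000094
 median interval: (1.382585, 1.520007)
     cp interval: (0.679260, 2.271930)
 blaker interval: (0.687274, 2.242454)
   midq interval: (0.743797, 2.196512)
   midp interval: (0.732235, 2.209981)
indices: jaccard=0.411765 sorensen_dice=0.583333 simpson=0.700000
```

Reading: 35 co-occurrences is far above the null expectation
`50·70/150 = 23.3`, giving a strongly positive affinity `α̂ = 1.455814`
(odds ratio `e^1.46 ≈ 4.3`). The CP interval is the widest of the four;
Blaker is nested inside it; midQ/midP are narrower with near-nominal
coverage. The short median interval (width 0.14) says discreteness adds
little ambiguity here.

The same analysis over every entity pair of a matrix:

```bash
cooccur-affinity simulate --entities 6 --sites 80 --pair 1:2:2.0 --seed 7 --out demo.csv
cooccur-affinity matrix demo.csv --axis rows --out demo --heatmap alpha_mle
cooccur-affinity coverage 50 70 150 --out cov --plot cov.png
```

Library use mirrors the CLI: `ml_alpha`, `interval_set`,
`coverage_curve`, `pairwise_affinity`, `sample_matrix` — see the module
docstrings under `src/cooccur_affinity/`.

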