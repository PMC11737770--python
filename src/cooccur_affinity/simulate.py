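"""Synthetic co-occurrence data under the two-species urn model.

The generative story: species A occupies ``mA`` of the ``N`` sites
uniformly at random; species B then occupies each site independently with
probability ``p1`` where A is present and ``p2`` where it is absent.
Conditioning on B's total ``mB``, the co-occurrence count depends on
``(p1, p2)`` only through the log odds ratio

    alpha = log[ p1 (1 - p2) / (p2 (1 - p1)) ],

and follows the Extended Hypergeometric distribution.  The fast samplers
here draw the count directly from that conditional law; the site-by-site
mechanism with rejection on B's total is kept as a slow validation path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distribution import TableMargins, sample
from .estimation import Table2x2


@dataclass(frozen=True)
class UrnConfig:
    """Study conditions for one species pair: margins plus the true
    affinity, given either directly as ``alpha`` or via the occupancy
    probabilities ``(p1, p2)`` which imply it."""

    mA: int
    mB: int
    N: int
    alpha: float | None = None
    p1: float | None = None
    p2: float | None = None

    def __post_init__(self) -> None:
        have_p = self.p1 is not None or self.p2 is not None
        if have_p:
            if self.p1 is None or self.p2 is None:
                raise ValueError("p1 and p2 must be given together")
            if not (0.0 < self.p1 < 1.0 and 0.0 < self.p2 < 1.0):
                raise ValueError("p1, p2 must lie strictly in (0, 1)")
            implied = math.log(self.p1 * (1 - self.p2) / (self.p2 * (1 - self.p1)))
            if self.alpha is not None and abs(self.alpha - implied) > 1e-12:
                raise ValueError(
                    f"alpha={self.alpha} inconsistent with (p1, p2) which "
                    f"imply {implied}"
                )
            object.__setattr__(self, "alpha", implied)
        elif self.alpha is None:
            raise ValueError("either alpha or (p1, p2) must be given")

    @property
    def margins(self) -> TableMargins:
        return TableMargins(self.mA, self.mB, self.N)


def sample_table(
    config: UrnConfig,
    n_rep: int = 1,
    rng: np.random.Generator | int | None = None,
) -> list[Table2x2]:
    """Draw ``n_rep`` tables with the config's margins and co-occurrence
    counts from the Extended Hypergeometric conditional law."""
    m = config.margins
    xs = sample(m, config.alpha, n_rep, rng)
    return [Table2x2(int(x), m) for x in xs]


def sample_counts(
    config: UrnConfig,
    n_rep: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Like :func:`sample_table` but returns the bare counts."""
    return sample(config.margins, config.alpha, n_rep, rng)


def sample_count_mechanism(
    config: UrnConfig,
    n_rep: int,
    rng: np.random.Generator | int | None = None,
    max_tries: int = 1_000_000,
) -> np.ndarray:
    """Slow validation path: simulate the site-by-site mechanism (B occupies
    A-sites w.p. p1 and others w.p. p2) and reject until B's total equals
    mB.  Requires a config built from ``(p1, p2)``."""
    if config.p1 is None:
        raise ValueError("mechanism sampling needs (p1, p2)")
    rng = np.random.default_rng(rng)
    out = np.empty(n_rep, dtype=int)
    for i in range(n_rep):
        for _ in range(max_tries):
            on_a = rng.random(config.mA) < config.p1
            off_a = rng.random(config.N - config.mA) < config.p2
            if on_a.sum() + off_a.sum() == config.mB:
                out[i] = on_a.sum()
                break
        else:
            raise RuntimeError(
                f"no draw matched mB={config.mB} in {max_tries} tries"
            )
    return out


def sample_matrix(
    n_entities: int,
    N: int,
    prevalences: list[int] | np.ndarray,
    pair_alphas: dict[tuple[int, int], float] | None = None,
    rng: np.random.Generator | int | None = None,
    entity_prefix: str = "sp",
    site_prefix: str = "site",
) -> pd.DataFrame:
    """Generate an entity-by-site presence-absence matrix.

    Each entity occupies exactly its requested number of sites.  Entities
    not named in ``pair_alphas`` choose their sites uniformly
    (independence, alpha = 0).  For a pair ``(i, j) -> alpha`` the
    co-occurrence count is drawn from the Extended Hypergeometric with that
    alpha and the overlap placed uniformly; each entity may appear in at
    most one specified pair (higher-order affinity is outside the model).

    Returns a DataFrame with entity rows and site columns of 0/1 ints.
    """
    rng = np.random.default_rng(rng)
    prevalences = np.asarray(prevalences, dtype=int)
    if len(prevalences) != n_entities:
        raise ValueError("one prevalence per entity is required")
    if np.any(prevalences < 0) or np.any(prevalences > N):
        raise ValueError("prevalences must lie in [0, N]")
    pair_alphas = dict(pair_alphas or {})
    seen: set[int] = set()
    for (i, j) in pair_alphas:
        if not (0 <= i < n_entities and 0 <= j < n_entities) or i == j:
            raise ValueError(f"invalid pair ({i}, {j})")
        if i in seen or j in seen:
            raise ValueError(
                f"entity in pair ({i}, {j}) already belongs to another "
                f"specified pair; pairwise affinities must be disjoint"
            )
        seen.update((i, j))

    mat = np.zeros((n_entities, N), dtype=int)
    for (i, j), alpha in pair_alphas.items():
        mA, mB = int(prevalences[i]), int(prevalences[j])
        margins = TableMargins(mA, mB, N)
        if margins.is_degenerate:
            x = margins.kmin
        else:
            x = int(sample(margins, alpha, 1, rng)[0])
        sites = rng.permutation(N)
        both = sites[:x]
        only_a = sites[x: x + (mA - x)]
        only_b = sites[x + (mA - x): x + (mA - x) + (mB - x)]
        mat[i, np.concatenate([both, only_a])] = 1
        mat[j, np.concatenate([both, only_b])] = 1
    for i in range(n_entities):
        if i not in seen:
            mat[i, rng.choice(N, size=int(prevalences[i]), replace=False)] = 1

    return pd.DataFrame(
        mat,
        index=[f"{entity_prefix}{i + 1}" for i in range(n_entities)],
        columns=[f"{site_prefix}{j + 1}" for j in range(N)],
    )
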