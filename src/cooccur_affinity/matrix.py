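"""Presence-absence matrix pipeline: preparation, pairwise affinity, output.

A matrix of entities by elements (e.g. species by sites) is validated and,
if it holds abundances, thresholded to binary.  Every unordered pair of
entities along the chosen axis is then reduced to a 2x2 table
(X = joint-presence count, mA/mB = entity totals, N = number of elements)
and run through the full affinity analysis: conditional MLE, median
interval, the four confidence intervals, the null-model summary and the
traditional similarity indices.  Results come back as a long-format
DataFrame with one row per pair, convertible to square matrices per field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distribution import DEFAULT_CAP, DegenerateTableError, TableMargins
from .estimation import Table2x2, ml_alpha, null_summary, traditional_indices
from .intervals import interval_set

logger = logging.getLogger(__name__)

#: Numeric columns of the long-format output, in order.
RECORD_COLUMNS = [
    "entity_1", "entity_2", "X", "mA", "mB", "N",
    "alpha_mle", "log_likelihood", "exp_cooccur", "p_value",
    "median_lo", "median_hi", "cp_lo", "cp_hi", "blaker_lo", "blaker_hi",
    "midq_lo", "midq_hi", "midp_lo", "midp_hi",
    "jaccard", "sorensen_dice", "simpson",
    "is_extreme_low", "is_extreme_high", "is_capped", "one_sided",
    "degenerate", "reason",
]

#: Fields that may be pivoted into square matrices.
SQUARE_FIELDS = [
    "X", "alpha_mle", "log_likelihood", "exp_cooccur", "p_value",
    "median_lo", "median_hi", "cp_lo", "cp_hi", "blaker_lo", "blaker_hi",
    "midq_lo", "midq_hi", "midp_lo", "midp_hi",
    "jaccard", "sorensen_dice", "simpson",
]


@dataclass(frozen=True)
class PrepConfig:
    """How to turn a raw matrix into an analyzable binary one.

    ``datatype`` is "binary" or "abundance"; abundance matrices need a
    ``threshold`` and a ``class0_rule`` saying whether a value exactly at
    the threshold counts as absence ("absence-at-threshold", i.e. presence
    requires value > threshold) or presence ("presence-at-threshold",
    presence is value >= threshold).  ``axis`` selects whether pairs are
    formed between rows or columns, and ``selection`` optionally restricts
    to a subset of labels along that axis.
    """

    datatype: str = "binary"
    threshold: float | None = None
    class0_rule: str = "absence-at-threshold"
    axis: str = "rows"
    selection: list[str] | None = None

    def __post_init__(self) -> None:
        if self.datatype not in ("binary", "abundance"):
            raise ValueError(f"datatype must be binary|abundance, got {self.datatype!r}")
        if self.axis not in ("rows", "cols"):
            raise ValueError(f"axis must be rows|cols, got {self.axis!r}")
        if self.class0_rule not in ("absence-at-threshold", "presence-at-threshold"):
            raise ValueError(f"unknown class0_rule {self.class0_rule!r}")
        if self.datatype == "abundance" and self.threshold is None:
            raise ValueError("abundance data requires a threshold")


def read_matrix(path, sep: str = ",", header: bool = True) -> pd.DataFrame:
    """Read a delimited entity-by-element matrix: header row = column
    labels, first column = row labels.  With ``header=False`` labels
    r1..rm / c1..cn are generated."""
    if header:
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        df.index = [f"r{i + 1}" for i in range(df.shape[0])]
        df.columns = [f"c{j + 1}" for j in range(df.shape[1])]
    return df


def _validate(df: pd.DataFrame) -> None:
    if df.size == 0:
        raise ValueError("matrix is empty")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate row labels: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column labels: {dups}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("matrix contains non-numeric values")
    if np.isnan(vals.astype(float)).any():
        i, j = np.argwhere(np.isnan(vals.astype(float)))[0]
        raise ValueError(
            f"missing value at row {df.index[i]!r}, column {df.columns[j]!r}; "
            f"a complete matrix is required so that N is common to all pairs"
        )
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )


def dataprep(df: pd.DataFrame, config: PrepConfig) -> pd.DataFrame:
    """Validate, subset and binarize a matrix according to ``config``.

    Declared-binary matrices must contain only 0/1; abundance matrices are
    thresholded with the boundary assigned by ``class0_rule``.
    """
    _validate(df)
    if config.selection is not None:
        labels = df.index if config.axis == "rows" else df.columns
        missing = [s for s in config.selection if s not in labels]
        if missing:
            raise KeyError(f"selection labels not found along {config.axis}: {missing}")
        df = df.loc[config.selection] if config.axis == "rows" else df[config.selection]
        if df.size == 0:
            raise ValueError("selection produced an empty matrix")
    vals = df.to_numpy()
    if config.datatype == "binary":
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"matrix declared binary but cell (row {df.index[i]!r}, "
                f"column {df.columns[j]!r}) holds {vals[i, j]!r}"
            )
        out = df.astype(int)
        logger.info("dataprep: binary matrix %s passed unchanged", out.shape)
        return out
    t = config.threshold
    if config.class0_rule == "absence-at-threshold":
        binary = (vals > t).astype(int)
    else:
        binary = (vals >= t).astype(int)
    out = pd.DataFrame(binary, index=df.index, columns=df.columns)
    logger.info(
        "dataprep: thresholded abundance matrix %s at %g (%s); %d cells set",
        out.shape, t, config.class0_rule, int(binary.sum()),
    )
    return out


def _pair_record(label_a: str, label_b: str, a: np.ndarray, b: np.ndarray,
                 N: int, level: float, cap: float) -> dict:
    X = int(np.sum((a == 1) & (b == 1)))
    mA, mB = int(a.sum()), int(b.sum())
    rec: dict = {
        "entity_1": label_a, "entity_2": label_b,
        "X": X, "mA": mA, "mB": mB, "N": N,
        "degenerate": False, "reason": "",
        "is_extreme_low": False, "is_extreme_high": False,
        "is_capped": False, "one_sided": False,
    }
    table = Table2x2(X, TableMargins(mA, mB, N))
    idx = traditional_indices(table)
    rec.update(jaccard=idx.jaccard, sorensen_dice=idx.sorensen_dice,
               simpson=idx.simpson)
    ns = null_summary(table)
    rec["exp_cooccur"] = ns.expected_cooccurrence
    try:
        est = ml_alpha(table, cap)
        ints = interval_set(table, level, cap)
    except DegenerateTableError:
        rec.update(degenerate=True,
                   reason=f"mA or mB in {{0, N={N}}}: alpha not estimable",
                   alpha_mle=math.nan, log_likelihood=math.nan,
                   p_value=math.nan)
        for k in ("median", "cp", "blaker", "midq", "midp"):
            rec[f"{k}_lo"] = math.nan
            rec[f"{k}_hi"] = math.nan
        return rec
    rec.update(
        alpha_mle=est.estimate, log_likelihood=est.log_likelihood,
        p_value=ns.p_value,
        is_extreme_low=est.is_extreme_low, is_extreme_high=est.is_extreme_high,
        is_capped=est.is_capped,
    )
    for key, ci in ints.as_dict().items():
        rec[f"{key}_lo"] = ci.lower
        rec[f"{key}_hi"] = ci.upper
        rec["one_sided"] = rec["one_sided"] or ci.one_sided
    return rec


def pairwise_affinity(
    df: pd.DataFrame,
    config: PrepConfig | None = None,
    level: float = 0.95,
    cap: float = DEFAULT_CAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Affinity analysis of every unordered entity pair along the chosen axis.

    Returns ``(records, prepared)``: the long-format results (one row per
    pair, sorted by label pair) and the processed binary matrix the
    analysis actually used.  Entities with prevalence 0 or N yield rows
    with missing estimates and a reason code rather than being dropped.
    """
    config = config or PrepConfig()
    prepped = dataprep(df, config)
    work = prepped if config.axis == "rows" else prepped.T
    if work.shape[0] < 2:
        raise ValueError(
            f"need at least 2 entities along {config.axis}, got {work.shape[0]}"
        )
    N = work.shape[1]
    labels = sorted(work.index)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            rows.append(_pair_record(la, lb, work.loc[la].to_numpy(),
                                     work.loc[lb].to_numpy(), N, level, cap))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return records, prepped


def squareform(records: pd.DataFrame, field: str) -> pd.DataFrame:
    """Pivot one numeric field of the long-format output into a symmetric
    entity-by-entity matrix (diagonal NaN: self-pairs are undefined)."""
    if field not in SQUARE_FIELDS:
        raise KeyError(
            f"unknown or non-pivotable field {field!r}; choose from {SQUARE_FIELDS}"
        )
    labels = sorted(set(records["entity_1"]) | set(records["entity_2"]))
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for _, r in records.iterrows():
        v = float(r[field])
        out.loc[r["entity_1"], r["entity_2"]] = v
        out.loc[r["entity_2"], r["entity_1"]] = v
    return out
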