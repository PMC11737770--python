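"""Matplotlib figures: pairwise-affinity heatmaps and coverage diagnostics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .coverage import CoverageCurve, coverage_summary
from .matrix import SQUARE_FIELDS, squareform


def plot_heatmap(records: pd.DataFrame, field: str, path,
                 cmap: str = "RdBu_r", title: str | None = None):
    """Symmetric heatmap of one numeric field of the pairwise output.

    Cells whose estimate was capped or sits at a support extreme are
    hatched: such values stand in for essentially infinite affinities and
    must not be read on the same scale as the rest.
    """
    if records.empty:
        raise ValueError("no records to plot")
    if field not in SQUARE_FIELDS:
        raise ValueError(
            f"field {field!r} is not a numeric pairwise quantity; "
            f"choose from {SQUARE_FIELDS}"
        )
    grid = squareform(records, field)
    labels = list(grid.index)
    flagged = set()
    for _, r in records.iterrows():
        if r["is_capped"] or r["is_extreme_low"] or r["is_extreme_high"]:
            flagged.add((r["entity_1"], r["entity_2"]))
            flagged.add((r["entity_2"], r["entity_1"]))

    fig, ax = plt.subplots(figsize=(1.0 + 0.5 * len(labels),) * 2)
    data = np.ma.masked_invalid(grid.to_numpy(dtype=float))
    vmax = np.nanmax(np.abs(grid.to_numpy(dtype=float))) if data.count() else 1.0
    kwargs = {"cmap": cmap}
    if field == "alpha_mle":
        kwargs.update(vmin=-vmax, vmax=vmax)
    im = ax.imshow(data, **kwargs)
    for (a, b) in flagged:
        i, j = labels.index(a), labels.index(b)
        ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                   hatch="///", edgecolor="black", lw=0.5))
    ax.set_xticks(range(len(labels)), labels, rotation=90)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_title(title or field)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_coverage(curves: list[CoverageCurve], path):
    """Per interval type: a coverage-vs-alpha panel (nominal level dashed)
    and a histogram of coverage values split below/above nominal with the
    percentages annotated."""
    if not curves:
        raise ValueError("no coverage curves to plot")
    n = len(curves)
    fig, axes = plt.subplots(n, 2, figsize=(10, 3.0 * n), squeeze=False)
    for row, curve in zip(axes, curves):
        s = coverage_summary(curve)
        ax = row[0]
        ax.plot(curve.alphas, curve.values, lw=1, color="C0")
        ax.axhline(curve.level, ls="--", color="red", lw=1)
        ax.set_xlabel(r"$\alpha$")
        ax.set_ylabel("coverage")
        ax.set_title(
            f"{curve.ci_type}: exact coverage, margins "
            f"({curve.margins.mA}, {curve.margins.mB}, {curve.margins.N})"
        )
        ax = row[1]
        v = curve.breakpoint_values
        below = v[v < curve.level]
        above = v[v >= curve.level]
        ax.hist([below, above], bins=20, stacked=False,
                color=["firebrick", "seagreen"],
                label=[
                    f"below nominal: {100 * s.fraction_below_nominal:.1f}%",
                    f"at/above: {100 * (1 - s.fraction_below_nominal):.1f}%",
                ])
        ax.axvline(curve.level, ls="--", color="red", lw=1)
        ax.set_xlabel("coverage")
        ax.set_ylabel("count")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
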