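"""Depolarization read-outs from per-cell intensity tables.

The voltage dye DiBAC4(3) accumulates in depolarized cells, so a cell's mean
fluorescence orders it on a depolarization axis.  The population read-outs
implemented here are the ones standard in single-cell bacterial Vmem work:

* a depolarization threshold set at the pooled mean intensity of control
  cells (:func:`depolarization_threshold`);
* the percentage of cells strictly above that threshold, summarized per
  biological replicate and then as mean +/- SEM across replicates
  (:func:`percent_depolarized`);
* intensity histograms pooled across replicates and normalized to the modal
  bin height (:func:`mode_normalized_histogram`).

Ties at exactly the threshold count as polarized ("above" is strict), and
SEM is always across biological replicates, never across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSpec",
    "ConditionSummary",
    "HistogramSpec",
    "depolarization_threshold",
    "percent_depolarized",
    "summarize_conditions",
    "mode_normalized_histogram",
    "summarize_experiment",
    "plot_histogram",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A depolarization threshold with its provenance.

    ``value`` is the arithmetic mean intensity of the ``n_cells_used``
    control cells pooled across replicates.
    """

    value: float
    control_condition: str
    n_cells_used: int

    def __post_init__(self) -> None:
        if self.n_cells_used <= 0:
            raise ValueError("a threshold must be based on at least one cell")


@dataclass(frozen=True)
class ConditionSummary:
    """Percent-depolarized summary of one condition across replicates."""

    condition: str
    per_replicate_pct: dict[str, float]
    mean_pct: float
    sem_pct: float
    n_cells_total: int

    @property
    def mean_fraction(self) -> float:
        return self.mean_pct / 100.0


@dataclass(frozen=True)
class HistogramSpec:
    """Mode-normalized intensity histogram of a pooled condition."""

    bin_edges: np.ndarray
    raw_counts: np.ndarray
    normalized_heights: np.ndarray
    threshold_marker: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "raw_count": self.raw_counts,
                "normalized": self.normalized_heights,
            }
        )


def depolarization_threshold(
    control: pd.DataFrame, control_condition: str | None = None
) -> ThresholdSpec:
    """Set the depolarization threshold at the mean control-cell intensity.

    Cells are pooled across all control replicates (not a mean of replicate
    means), matching the convention of averaging the control population's
    dye fluorescence directly.
    """
    if control_condition is not None:
        control = control[control["condition"] == control_condition]
    if len(control) == 0:
        raise ValueError("no control cells: cannot set a depolarization threshold")
    name = (
        control_condition
        if control_condition is not None
        else str(control["condition"].iloc[0]) if "condition" in control else "control"
    )
    return ThresholdSpec(
        value=float(control["mean_intensity"].mean()),
        control_condition=name,
        n_cells_used=int(len(control)),
    )


def percent_depolarized(table: pd.DataFrame, threshold: ThresholdSpec) -> ConditionSummary:
    """Percentage of cells strictly above the threshold, per replicate.

    ``table`` must hold a single condition; the summary's ``mean_pct`` and
    ``sem_pct`` are the mean and standard error of the per-replicate
    percentages (SEM is NaN with a single replicate).
    """
    if len(table) == 0:
        raise ValueError("empty cell table")
    conditions = table["condition"].unique()
    if len(conditions) > 1:
        raise ValueError(
            f"table mixes conditions {sorted(map(str, conditions))}; "
            "summarize one condition at a time (see summarize_conditions)"
        )
    if table["replicate"].isna().any():
        raise ValueError("every cell needs a replicate label")

    pcts: dict[str, float] = {}
    for rep, grp in table.groupby("replicate", sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"replicate {rep} has no cells; excluded", stacklevel=2)
            continue
        pcts[str(rep)] = 100.0 * float(
            (grp["mean_intensity"] > threshold.value).mean()
        )
    values = np.array(list(pcts.values()), dtype=float)
    sem = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return ConditionSummary(
        condition=str(conditions[0]),
        per_replicate_pct=pcts,
        mean_pct=float(values.mean()),
        sem_pct=sem,
        n_cells_total=int(len(table)),
    )


def summarize_conditions(
    table: pd.DataFrame, threshold: ThresholdSpec
) -> list[ConditionSummary]:
    """Apply :func:`percent_depolarized` to every condition in a pooled table."""
    return [
        percent_depolarized(grp, threshold)
        for _, grp in table.groupby("condition", sort=True)
    ]


def mode_normalized_histogram(
    tables: pd.DataFrame | list[pd.DataFrame],
    bin_width: float = 1.0,
    threshold: ThresholdSpec | None = None,
) -> HistogramSpec:
    """Histogram of pooled intensities, heights normalized to the modal bin.

    Replicate tables of the same condition are pooled before binning; bins
    are fixed-width from 0 to the maximum observed intensity, and heights
    are divided by the count of the most frequent bin so the mode is 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise ValueError("no tables supplied")
    values = pd.concat(tables, ignore_index=True)["mean_intensity"].to_numpy(float)
    if values.size == 0:
        raise ValueError("no cells to histogram")
    top = max(values.max(), bin_width)
    n_bins = int(np.ceil(top / bin_width)) + 1  # last edge strictly above max
    edges = np.arange(0.0, (n_bins + 0.5) * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return HistogramSpec(
        bin_edges=edges,
        raw_counts=counts,
        normalized_heights=counts / counts.max(),
        threshold_marker=None if threshold is None else threshold.value,
    )


def summarize_experiment(summaries: list[ConditionSummary]) -> dict[str, pd.DataFrame]:
    """Tidy the per-condition summaries for statistics and plotting.

    Returns ``{"per_replicate": ..., "by_condition": ...}`` where
    ``per_replicate`` has one row per (condition, replicate) percentage and
    ``by_condition`` carries mean +/- SEM and total cell counts.
    """
    if not summaries:
        raise ValueError("no condition summaries supplied")
    per_rep = pd.DataFrame(
        [
            {"condition": s.condition, "replicate": rep, "pct": pct}
            for s in summaries
            for rep, pct in s.per_replicate_pct.items()
        ]
    )
    by_cond = pd.DataFrame(
        [
            {
                "condition": s.condition,
                "mean_pct": s.mean_pct,
                "sem_pct": s.sem_pct,
                "n_cells": s.n_cells_total,
            }
            for s in summaries
        ]
    )
    return {"per_replicate": per_rep, "by_condition": by_cond}


def plot_histogram(hist: HistogramSpec, ax=None, **bar_kwargs):
    """Bar plot of a mode-normalized histogram with a dashed threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    widths = np.diff(hist.bin_edges)
    ax.bar(centers, hist.normalized_heights, width=widths, align="center", **bar_kwargs)
    if hist.threshold_marker is not None:
        ax.axvline(hist.threshold_marker, linestyle="--", color="k")
    ax.set_xlabel("DiBAC fluorescence intensity (a.u.)")
    ax.set_ylabel("cells (normalized to mode)")
    return ax
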