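"""Fold-change event filters and the event-count gene ranking.

Differential expression is called purely by fold change on log2 ratios. Three
filters are provided, each reading the same probes x events matrix from a
different angle:

* cell-line filter — within one cell line, keep probes changed at least
  ``fc2``-fold at one or more of the six time points;
* time-point filter — across cell lines, keep probes changed at least
  ``fc2``-fold at one given time point;
* general filter — across all events of one ligand, keep probes changed at
  least ``fc3``-fold in >= ``general_min_events_fc3`` events and/or at least
  ``fc2``-fold in >= ``general_min_events_fc2`` events (the two clauses are a
  logical OR, and an event beyond the stronger cutoff also counts toward the
  weaker one).

An *event* is one (cell line, time point) column of the ligand's matrix; with
five cell lines and six time points a gene can be regulated in at most 30
events, which is the ranking statistic's ceiling. Thresholds are inclusive
(>= log2 fold change) and missing values never count as regulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import CANONICAL_TIMES, ExpressionMatrix, ValidationError


@dataclass(frozen=True)
class FilterConfig:
    fc2_threshold: float = 2.0
    fc3_threshold: float = 3.0
    general_min_events_fc3: int = 3
    general_min_events_fc2: int = 4

    def __post_init__(self) -> None:
        if not (self.fc3_threshold >= self.fc2_threshold > 1):
            raise ValidationError("need fc3_threshold >= fc2_threshold > 1")
        if self.general_min_events_fc3 < 1 or self.general_min_events_fc2 < 1:
            raise ValidationError("event minima must be >= 1")


@dataclass(frozen=True)
class GeneEventCount:
    gene_id: str
    up_events: int
    down_events: int

    @property
    def total_events(self) -> int:
        return self.up_events + self.down_events


def is_regulated(log2_ratio: float, fold_threshold: float) -> str:
    """Classify one log2 ratio as 'up', 'down' or 'none' at a fold cutoff."""
    if fold_threshold <= 1:
        raise ValidationError(f"fold threshold must exceed 1, got {fold_threshold}")
    if not np.isfinite(log2_ratio):
        raise ValidationError(f"non-finite log2 ratio: {log2_ratio}")
    cut = np.log2(fold_threshold)
    if log2_ratio >= cut:
        return "up"
    if log2_ratio <= -cut:
        return "down"
    return "none"


def _single_line(matrix: ExpressionMatrix) -> None:
    pairs = {(e.cell_line, e.ligand) for e in matrix.events}
    if len(pairs) != 1:
        raise ValidationError(f"expected one (cell line, ligand), got {sorted(pairs)}")
    if matrix.data.shape[1] != len(CANONICAL_TIMES):
        raise ValidationError(
            f"expected {len(CANONICAL_TIMES)} time points, got {matrix.data.shape[1]}"
        )


def cellline_filter(matrix: ExpressionMatrix, config: FilterConfig = FilterConfig()) -> list[str]:
    """Probes changed >= fc2-fold at >= 1 time point of one cell line.

    Probes with any missing value in this cell line are excluded outright.
    """
    _single_line(matrix)
    cut = np.log2(config.fc2_threshold)
    complete = matrix.data.notna().all(axis=1)
    hit = (matrix.data.abs() >= cut).any(axis=1)
    keep = matrix.data.index[complete & hit]
    return list(keep)


def timepoint_filter(
    matrix: ExpressionMatrix, time_point: float, config: FilterConfig = FilterConfig()
) -> list[str]:
    """Probes changed >= fc2-fold at the given time point in >= 1 cell line."""
    cols = [e.token for e in matrix.events if e.time_point == time_point]
    if not cols:
        raise ValidationError(f"time point {time_point!r} not present in matrix")
    cut = np.log2(config.fc2_threshold)
    hit = (matrix.data[cols].abs() >= cut).any(axis=1)
    return list(matrix.data.index[hit])


def general_filter(matrix: ExpressionMatrix, config: FilterConfig = FilterConfig()) -> list[str]:
    """Probes >= fc3-fold in >= 3 events and/or >= fc2-fold in >= 4 events.

    The matrix must contain the events of a single ligand; missing values
    count as not-regulated.
    """
    if len(matrix.ligands) != 1:
        raise ValidationError(f"general filter needs a single ligand, got {matrix.ligands}")
    absvals = matrix.data.abs()
    n_fc3 = (absvals >= np.log2(config.fc3_threshold)).sum(axis=1)
    n_fc2 = (absvals >= np.log2(config.fc2_threshold)).sum(axis=1)
    keep = (n_fc3 >= config.general_min_events_fc3) | (n_fc2 >= config.general_min_events_fc2)
    return list(matrix.data.index[keep])


def count_events(
    matrix: ExpressionMatrix, probe_id: str, config: FilterConfig = FilterConfig(),
    gene_id: str | None = None,
) -> GeneEventCount:
    """Tally up/down regulation events for one probe at the fc2 cutoff."""
    if probe_id not in matrix.data.index:
        raise KeyError(f"unknown probe id {probe_id!r}")
    row = matrix.data.loc[probe_id]
    cut = np.log2(config.fc2_threshold)
    up = int((row >= cut).sum())
    down = int((row <= -cut).sum())
    return GeneEventCount(gene_id=gene_id or probe_id, up_events=up, down_events=down)


def count_events_table(
    matrix: ExpressionMatrix,
    probe_to_gene: dict[str, str] | None = None,
    config: FilterConfig = FilterConfig(),
    probe_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene event counts over the whole matrix (vectorized).

    When ``probe_to_gene`` is given, only probes in the map (the uniquely
    annotated ones) are counted and a gene with several probes is represented
    by its probe with the largest total event count (tie: lexicographically
    first probe id).
    """
    data = matrix.data if probe_ids is None else matrix.data.loc[probe_ids]
    cut = np.log2(config.fc2_threshold)
    up = (data >= cut).sum(axis=1).astype(int)
    down = (data <= -cut).sum(axis=1).astype(int)
    table = pd.DataFrame({"probe_id": data.index, "up_events": up.values,
                          "down_events": down.values})
    table["total_events"] = table["up_events"] + table["down_events"]
    if probe_to_gene is None:
        table["gene_id"] = table["probe_id"]
    else:
        table = table[table["probe_id"].isin(probe_to_gene)].copy()
        table["gene_id"] = table["probe_id"].map(probe_to_gene)
        table = (
            table.sort_values(["gene_id", "total_events", "probe_id"],
                              ascending=[True, False, True])
            .drop_duplicates("gene_id", keep="first")
        )
    return table[["gene_id", "probe_id", "up_events", "down_events", "total_events"]].reset_index(drop=True)


def rank_genes(counts: pd.DataFrame, min_total: int = 1) -> pd.DataFrame:
    """Rank genes by total regulation events.

    Descending by total, ties broken by up_events descending then gene_id
    ascending; rows with total_events < ``min_total`` are dropped.
    """
    kept = counts[counts["total_events"] >= min_total].copy()
    kept = kept.sort_values(
        ["total_events", "up_events", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    kept.insert(0, "rank", np.arange(1, len(kept) + 1))
    return kept


def up_fraction(ranked: pd.DataFrame, top_n: int) -> float:
    """Fraction of regulation events that are upregulation among the top rows."""
    if top_n <= 0:
        raise ValidationError("top_n must be positive")
    if top_n > len(ranked):
        raise ValidationError(f"top_n={top_n} exceeds table size {len(ranked)}")
    head = ranked.iloc[:top_n]
    total = int(head["total_events"].sum())
    if total == 0:
        raise ValidationError("no regulation events in the selected rows")
    return float(head["up_events"].sum()) / total
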