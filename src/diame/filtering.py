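"""Filtering rules applied before metric computation.

Precursor-level q-value filtering (run-wise and global q-values at 1%, global
protein-group q at 1%, optional run-wise protein-group q at a moderate cutoff),
matching-enhancer (ME) run exclusion, contaminant removal, and the count-based
matrix filters used for single-cell data (minimum proteins per cell, minimum
replicates per group, maximum missing fraction).

All filters only remove records/rows/columns and are idempotent. ME exclusion
must run before re-normalization; the pipeline module enforces that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .report_io import ReportFormatError, ReportTable

__all__ = [
    "FilterConfig",
    "apply_qvalue_filters",
    "drop_me_runs",
    "filter_contaminants",
    "filter_cells_min_proteins",
    "filter_min_group_replicates",
    "filter_max_missing",
]

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the default filtering scheme.

    ``pgq_run_max`` is off by default (the run-wise protein-group q-value is not
    part of the default filter set); 0.05 is the recommended moderate cutoff when
    enabled.
    """

    q_run_max: float = 0.01
    q_global_max: float = 0.01
    pgq_global_max: float = 0.01
    pgq_run_max: float | None = None
    min_proteins_per_cell: int = 500
    min_replicates_per_group: int = 3
    max_missing_fraction: float = 0.70
    contaminant_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("q_run_max", "q_global_max", "pgq_global_max", "max_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pgq_run_max is not None and not 0.0 <= self.pgq_run_max <= 1.0:
            raise ValueError(f"pgq_run_max must lie in [0, 1], got {self.pgq_run_max}")
        if self.min_proteins_per_cell < 1 or self.min_replicates_per_group < 1:
            raise ValueError("count thresholds must be >= 1")


def apply_qvalue_filters(table: ReportTable, cfg: FilterConfig | None = None) -> ReportTable:
    """Keep records passing every enabled q-value threshold (NaN q-values fail)."""
    cfg = cfg or FilterConfig()
    df = table.df
    keep = (
        (df["q_run"] <= cfg.q_run_max)
        & (df["q_global"] <= cfg.q_global_max)
        & (df["pgq_global"] <= cfg.pgq_global_max)
    )
    if cfg.pgq_run_max is not None:
        keep &= df["pgq_run"] <= cfg.pgq_run_max
    return ReportTable(df[keep.fillna(False)].copy())


def drop_me_runs(table: ReportTable, annotations: pd.DataFrame) -> ReportTable:
    """Exclude matching-enhancer (and blank) runs, keeping analyte records only.

    Every run in the table must be annotated; run order is preserved.
    """
    roles = dict(zip(annotations["run_id"], annotations["role"]))
    unannotated = [r for r in table.runs if r not in roles]
    if unannotated:
        raise ReportFormatError(f"unannotated runs: {unannotated}")
    analyte_runs = [r for r in table.runs if roles[r] == "analyte"]
    if not analyte_runs:
        log.warning("drop_me_runs: no analyte runs remain")
    return table.subset_runs(analyte_runs)


def _group_hits(protein_group: str, contaminants: set[str]) -> bool:
    return any(m in contaminants for m in str(protein_group).split(";"))


def filter_contaminants(data: ReportTable | pd.DataFrame, contaminant_ids: set[str]):
    """Remove records/rows whose protein group intersects the contaminant list.

    Matching is by exact identifier within the semicolon-split protein group.
    Accepts a :class:`ReportTable` or a protein matrix and returns the same kind.
    """
    if not contaminant_ids:
        return data
    if isinstance(data, ReportTable):
        hits = data.df["protein_group"].map(lambda g: _group_hits(g, contaminant_ids))
        return ReportTable(data.df[~hits].copy())
    hits = [_group_hits(g, contaminant_ids) for g in data.index]
    return data.loc[[not h for h in hits]]


def filter_cells_min_proteins(matrix: pd.DataFrame, min_n: int = 500) -> pd.DataFrame:
    """Drop sample columns (cells) with fewer than ``min_n`` observed proteins."""
    counts = matrix.notna().sum(axis=0)
    dropped = counts.index[counts < min_n]
    if len(dropped):
        log.info("filter_cells_min_proteins: dropping %d cells below %d proteins", len(dropped), min_n)
    return matrix.loc[:, counts >= min_n]


def filter_min_group_replicates(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    min_k: int = 3,
    mode: str = "any",
) -> pd.DataFrame:
    """Keep proteins observed in >= ``min_k`` replicates per group.

    ``mode="any"`` requires the rule in at least one group (a protein testable in
    at least one time-point is kept); ``mode="all"`` requires it in every group.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    groups = pd.Series(groups)
    per_group = {}
    for g, cols in groups.groupby(groups).groups.items():
        cols = [c for c in cols if c in matrix.columns]
        if len(cols) < min_k:
            raise ValueError(f"group {g!r} has {len(cols)} columns, fewer than min_k={min_k}")
        per_group[g] = matrix[cols].notna().sum(axis=1) >= min_k
    counts = pd.DataFrame(per_group)
    keep = counts.any(axis=1) if mode == "any" else counts.all(axis=1)
    return matrix.loc[keep]


def filter_max_missing(matrix: pd.DataFrame, max_missing_fraction: float = 0.70) -> pd.DataFrame:
    """Exclude proteins observed in fewer than ``1 - max_missing_fraction`` of cells."""
    observed = matrix.notna().mean(axis=1)
    return matrix.loc[observed >= 1.0 - max_missing_fraction]
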