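"""Species-entrapment fidelity statistics.

A foreign proteome spiked into (or co-analyzed with) pure human samples turns
every foreign identification in a human-only run into a known error. From
per-replicate identification counts this module computes

* the false-positive rate, FPR = IDs_entrapment / IDs_total,
* the false-transfer rate, FTR = (IDs_entrapment,MBR - IDs_entrapment,Indiv) /
  (IDs_total,MBR - IDs_total,Indiv), the fraction of identifications gained by
  matching that hit the entrapment proteome, with the convention that a
  replicate losing human identifications while gaining entrapment ones is
  assigned 100%,
* protein-level FPR over distinct protein groups,
* ROC curves over any q-value column (human = positive class), and
* the Szymkiewicz-Simpson overlap and Jaccard coefficients between ID sets.

Shared-species records must be excluded before counting; :func:`counts_from_table`
does this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .report_io import ReportTable

__all__ = [
    "EntrapmentCounts",
    "RocCurve",
    "UndefinedMetricError",
    "counts_from_table",
    "false_positive_rate",
    "false_transfer_rate",
    "protein_level_fpr",
    "roc_over_qvalues",
    "overlap_coefficient",
    "jaccard_index",
    "ftr_table",
]

log = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a rate is requested on a degenerate (empty) replicate."""


@dataclass(frozen=True)
class EntrapmentCounts:
    """Per-replicate identification counts by species (after shared exclusion)."""

    replicate_id: str
    ids_human: int
    ids_entrapment: int
    mode: str  # "indiv" or "mbr"

    def __post_init__(self) -> None:
        if self.ids_human < 0 or self.ids_entrapment < 0:
            raise ValueError("identification counts must be non-negative")
        if self.mode not in ("indiv", "mbr"):
            raise ValueError(f"mode must be 'indiv' or 'mbr', got {self.mode!r}")

    @property
    def ids_total(self) -> int:
        return self.ids_human + self.ids_entrapment


@dataclass
class RocCurve:
    """ROC over q-value thresholds; human retained fraction vs entrapment retained fraction."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    qvalue_column: str


def counts_from_table(table: ReportTable, run_id: str, mode: str) -> EntrapmentCounts:
    """Count distinct human/entrapment precursors of one run.

    ``mode="indiv"`` restricts to first-pass identifications, emulating an
    individual (matching-disabled) analysis of the same data; ``mode="mbr"``
    counts everything. Shared and unknown species are excluded.
    """
    df = table.df
    sub = df[df["run_id"] == run_id]
    if mode == "indiv":
        sub = sub[sub["provenance"] == "first_pass"]
    counts = sub.drop_duplicates("precursor_id")["species"].value_counts()
    return EntrapmentCounts(
        replicate_id=run_id,
        ids_human=int(counts.get("human", 0)),
        ids_entrapment=int(counts.get("entrapment", 0)),
        mode=mode,
    )


def false_positive_rate(c: EntrapmentCounts) -> float:
    """Fraction of entrapment identifications among all identifications."""
    if c.ids_total == 0:
        raise UndefinedMetricError(f"replicate {c.replicate_id}: no identifications")
    return c.ids_entrapment / c.ids_total


def false_transfer_rate(mbr: EntrapmentCounts, indiv: EntrapmentCounts) -> float:
    """Fraction of entrapment identifications among identifications gained by matching.

    Returns NaN when matching gained nothing (degenerate denominator, no 100%
    convention applicable). Values above 1 are clipped to 1 with a warning.
    """
    if mbr.replicate_id != indiv.replicate_id:
        raise ValueError(f"replicate mismatch: {mbr.replicate_id!r} vs {indiv.replicate_id!r}")
    if mbr.mode != "mbr" or indiv.mode != "indiv":
        raise ValueError("false_transfer_rate expects (mbr, indiv) count modes")
    d_ent = mbr.ids_entrapment - indiv.ids_entrapment
    d_hum = mbr.ids_human - indiv.ids_human
    d_tot = mbr.ids_total - indiv.ids_total
    if d_hum < 0 and d_ent > 0:
        # fewer human but more entrapment identifications after matching
        return 1.0
    if d_tot <= 0:
        return float("nan")
    ftr = d_ent / d_tot
    if ftr > 1.0:
        log.warning("FTR %.3f > 1 clipped to 1 for replicate %s", ftr, mbr.replicate_id)
        return 1.0
    return max(ftr, 0.0)


def ftr_table(table: ReportTable, runs: list[str] | None = None) -> pd.DataFrame:
    """Per-replicate FPR/FTR summary derived from provenance labels.

    For each run the matching-disabled counterpart is the restriction to
    first-pass records. Undefined FTRs are NaN and excluded from means.
    """
    runs = runs if runs is not None else table.runs
    rows = []
    for run in runs:
        mbr = counts_from_table(table, run, "mbr")
        indiv = counts_from_table(table, run, "indiv")
        rows.append(
            {
                "run_id": run,
                "ids_human_indiv": indiv.ids_human,
                "ids_entrapment_indiv": indiv.ids_entrapment,
                "ids_human_mbr": mbr.ids_human,
                "ids_entrapment_mbr": mbr.ids_entrapment,
                "fpr": false_positive_rate(mbr) if mbr.ids_total else np.nan,
                "ftr": false_transfer_rate(mbr, indiv),
            }
        )
    return pd.DataFrame(rows)


def pooled_ftr(table: ReportTable, runs: list[str] | None = None) -> tuple[float, int]:
    """FTR pooled over replicates: summed count differences, returned with the
    pooled number of gained identifications."""
    runs = runs if runs is not None else table.runs
    d_ent = d_tot = 0
    for run in runs:
        mbr = counts_from_table(table, run, "mbr")
        indiv = counts_from_table(table, run, "indiv")
        d_ent += mbr.ids_entrapment - indiv.ids_entrapment
        d_tot += mbr.ids_total - indiv.ids_total
    if d_tot <= 0:
        return float("nan"), 0
    return d_ent / d_tot, d_tot


def protein_level_fpr(table: ReportTable, run_id: str | None = None) -> float:
    """Fraction of distinct entrapment protein groups among all distinct groups.

    Shared and unknown groups are excluded. Restrict to one replicate by
    ``run_id``; otherwise the whole table is treated as one replicate.
    """
    df = table.df
    if run_id is not None:
        df = df[df["run_id"] == run_id]
    df = df[df["species"].isin(["human", "entrapment"])]
    groups = df.drop_duplicates("protein_group")[["protein_group", "species"]]
    if len(groups) == 0:
        raise UndefinedMetricError("no protein groups after shared exclusion")
    return float((groups["species"] == "entrapment").mean())


def roc_over_qvalues(table: ReportTable | pd.DataFrame, qvalue_column: str = "q_run") -> RocCurve:
    """ROC sweeping every observed q-value as an acceptance threshold (keep if <= t).

    Human records form the positive class, entrapment the negative; the retained
    human fraction is the TPR and the retained entrapment fraction the FPR. The
    AUROC is the trapezoidal integral of TPR over FPR. Thresholds are anchored
    at 0 and 1 so the curve runs from (0, 0) to (1, 1).
    """
    df = table.df if isinstance(table, ReportTable) else table
    df = df[df["species"].isin(["human", "entrapment"])]
    q = df[qvalue_column].to_numpy(dtype=float)
    is_human = (df["species"] == "human").to_numpy()
    if is_human.all() or (~is_human).all() or len(df) == 0:
        raise UndefinedMetricError("ROC needs both human and entrapment records")
    thresholds = np.unique(np.concatenate([[0.0, 1.0], q]))
    n_pos, n_neg = is_human.sum(), (~is_human).sum()
    # retained fractions at q <= t, vectorized over sorted q
    order = np.argsort(q, kind="stable")
    q_sorted, human_sorted = q[order], is_human[order]
    cum_pos = np.concatenate([[0], np.cumsum(human_sorted)])
    cum_neg = np.concatenate([[0], np.cumsum(~human_sorted)])
    idx = np.searchsorted(q_sorted, thresholds, side="right")
    tpr = cum_pos[idx] / n_pos
    fpr = cum_neg[idx] / n_neg
    auroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auroc=auroc, qvalue_column=qvalue_column)


def overlap_coefficient(a: set, b: set) -> float:
    """Szymkiewicz-Simpson overlap coefficient |a & b| / min(|a|, |b|)."""
    if not a or not b:
        if not a and not b:
            raise UndefinedMetricError("overlap coefficient undefined for two empty sets")
        return 0.0
    return len(a & b) / min(len(a), len(b))


def jaccard_index(a: set, b: set) -> float:
    """Jaccard similarity coefficient |a & b| / |a | b|."""
    union = a | b
    if not union:
        raise UndefinedMetricError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)
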