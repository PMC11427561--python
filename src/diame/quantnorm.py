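"""ME-aware re-normalization, protein summarization and quantitative quality metrics.

Normalization model
-------------------
Between-run differences in injected amount and pipetting/loading are modelled as
a single additive shift per sample in log2 space (equivalently one multiplicative
factor on the linear scale). :func:`normalize_traces` estimates the shift of each
sample against an anchor (the sample with the most observations) as the log2
ratio of summed linear intensity over the ions the two samples share, and then
mean-centres the shifts so the overall intensity scale of the dataset is
preserved. Matching total signal rather than a median of ion ratios makes the
estimate composition-invariant: in a two-proteome mixture where a spike-in
replaces a weight fraction of the base proteome, total mass is conserved, so the
shared-ion totals reflect amount and loading only, while any quantile of the
per-ion ratio distribution would lock onto the majority species and flatten true
between-condition ratios. A ``method="median"`` variant (median pairwise ion
log-ratio to the anchor) is provided for comparison.

Because matching-enhancer (ME) runs carry ~10x the analyte input, they must be
excluded from the report before re-normalization: an ME run would become the
anchor and drag the centred shifts — and with them every analyte quantity —
toward the ME scale. The pipeline enforces this order.

Protein summarization aligns each ion's trace to the protein's consensus trace
by its median offset and takes the per-sample median across aligned ions,
so a protein's between-sample profile is driven by the consensus of its ions
rather than by which ions happen to be observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .report_io import ReportTable

__all__ = [
    "SpikeDesign",
    "NormalizationError",
    "normalize_traces",
    "summarize_protein",
    "summarize_proteins",
    "protein_cv",
    "expected_log2_ratio",
    "ratio_deviation",
    "completeness_bins",
    "sample_correlation",
    "pca_scores",
    "dynamic_range",
]

log = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """Raised when samples cannot be placed on a common scale."""


@dataclass
class SpikeDesign:
    """Per-condition spike fraction rho (w/w) and input amount (ng).

    ``conditions`` maps a condition name to ``(spike_fraction, input_amount)``.
    The spike replaces a weight fraction of the base proteome, so the expected
    log2 ratio between conditions b and a is ``log2(rho_b/rho_a)`` plus the
    amount ratio for the spiked species and ``log2((1-rho_b)/(1-rho_a))`` plus
    the amount ratio for the base species.
    """

    conditions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (rho, amount) in self.conditions.items():
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"condition {name!r}: spike fraction must lie in [0, 1), got {rho}")
            if amount <= 0:
                raise ValueError(f"condition {name!r}: input amount must be positive")


def _ion_matrix(table: ReportTable) -> pd.DataFrame:
    """Ion x run log2 intensity matrix (zero/missing intensities become NaN)."""
    df = table.df[table.df["intensity"] > 0]
    mat = df.pivot_table(index="precursor_id", columns="run_id", values="intensity", aggfunc="first")
    return np.log2(mat).reindex(columns=list(dict.fromkeys(table.df["run_id"])))


def normalize_traces(table: ReportTable, method: str = "mass") -> tuple[ReportTable, pd.Series]:
    """Re-normalize ion intensities with one additive log2 shift per sample.

    Returns the shifted table and the per-run shifts (mean-centred across runs).
    Within-sample ion ratios are untouched — the transform is shift-only.

    ``method="mass"`` (default) matches summed linear intensity over shared ions
    against the anchor; ``method="median"`` sets the median pairwise ion log-ratio
    to the anchor to zero.
    """
    mat = _ion_matrix(table)
    if mat.shape[1] == 0:
        raise NormalizationError("no runs with positive intensities")
    anchor = mat.notna().sum(axis=0).idxmax()
    anchor_vals = mat[anchor]
    provisional = {}
    for run in mat.columns:
        if run == anchor:
            provisional[run] = 0.0
            continue
        both = mat[run].notna() & anchor_vals.notna()
        if not both.any():
            raise NormalizationError(f"sample {run!r} shares no ions with the anchor {anchor!r}")
        if method == "mass":
            ratio = np.log2(np.exp2(mat.loc[both, run]).sum()) - np.log2(np.exp2(anchor_vals[both]).sum())
        elif method == "median":
            ratio = float((mat.loc[both, run] - anchor_vals[both]).median())
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        provisional[run] = -ratio
    shifts = pd.Series(provisional, dtype=float).reindex(mat.columns)
    shifts -= shifts.mean()
    df = table.df.copy()
    factors = df["run_id"].map(shifts)
    df["intensity"] = df["intensity"] * np.exp2(factors)
    shifts.name = "shift_log2"
    shifts.index.name = "run_id"
    return ReportTable(df), shifts


def summarize_protein(ion_traces: pd.DataFrame) -> pd.Series:
    """Collapse one protein's ion traces (ions x samples, log2) to a protein trace.

    Each ion is shifted by its median offset to the consensus trace (the
    per-sample median across ions); the protein value per sample is the median
    across aligned ions observed in that sample.
    """
    if ion_traces.shape[0] == 0:
        raise ValueError("summarize_protein needs at least one ion")
    if ion_traces.shape[0] == 1:
        return ion_traces.iloc[0]
    consensus = ion_traces.median(axis=0)
    offsets = ion_traces.sub(consensus, axis=1).median(axis=1)
    aligned = ion_traces.sub(offsets, axis=0)
    return aligned.median(axis=0)


def summarize_proteins(table: ReportTable, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Protein-group x run log2 matrix via per-protein trace alignment.

    When ``annotations`` are given only analyte runs form columns.
    """
    df = table.df[table.df["intensity"] > 0]
    if annotations is not None:
        analyte = set(annotations.loc[annotations["role"] == "analyte", "run_id"])
        df = df[df["run_id"].isin(analyte)]
    if df.empty:
        raise ValueError("no records to summarize")
    runs = list(dict.fromkeys(df["run_id"]))
    log2 = df.assign(log2=np.log2(df["intensity"]))
    rows = {}
    for protein, sub in log2.groupby("protein_group", sort=True):
        traces = sub.pivot_table(index="precursor_id", columns="run_id", values="log2", aggfunc="first")
        rows[protein] = summarize_protein(traces.reindex(columns=runs))
    mat = pd.DataFrame(rows).T.reindex(columns=runs)
    mat.index.name = "protein_group"
    mat.columns.name = "run_id"
    return mat


def protein_cv(matrix: pd.DataFrame, min_obs: int = 2) -> pd.Series:
    """Coefficient of variation of linear-scale intensities across replicate columns.

    sd (n-1) over mean per protein; proteins with fewer than ``min_obs``
    observations get NaN.
    """
    linear = np.exp2(matrix)
    n = linear.notna().sum(axis=1)
    cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
    cv[n < min_obs] = np.nan
    cv.name = "cv"
    return cv


def expected_log2_ratio(design: SpikeDesign, cond_a: str, cond_b: str, species: str) -> float:
    """Expected log2 ratio (condition b over a) for a species under the spike design."""
    if cond_a not in design.conditions or cond_b not in design.conditions:
        raise KeyError(f"conditions {cond_a!r}/{cond_b!r} not in design")
    rho_a, amt_a = design.conditions[cond_a]
    rho_b, amt_b = design.conditions[cond_b]
    if species == "entrapment":
        if rho_a == 0 or rho_b == 0:
            raise ValueError("entrapment ratio undefined for a non-spiked condition")
        return float(np.log2(rho_b / rho_a) + np.log2(amt_b / amt_a))
    if species == "human":
        return float(np.log2((1 - rho_b) / (1 - rho_a)) + np.log2(amt_b / amt_a))
    raise ValueError(f"no expected ratio for species {species!r}")


def ratio_deviation(
    matrix: pd.DataFrame,
    design: SpikeDesign,
    annotations: pd.DataFrame,
    species: pd.Series,
    cond_a: str,
    cond_b: str,
    summary: str = "median",
) -> pd.DataFrame:
    """Observed minus expected between-condition log2 ratio per protein.

    Condition values are the ``summary`` (median by default, or mean) over that
    condition's replicate columns; proteins need at least one value in each
    condition, others are excluded (their count is logged). ``species`` maps
    protein group -> species; shared/unknown proteins are excluded.
    """
    if summary not in ("median", "mean"):
        raise ValueError(f"summary must be 'median' or 'mean', got {summary!r}")
    cond_of = dict(zip(annotations["run_id"], annotations["condition"]))
    cols_a = [c for c in matrix.columns if cond_of.get(c) == cond_a]
    cols_b = [c for c in matrix.columns if cond_of.get(c) == cond_b]
    if not cols_a or not cols_b:
        raise ValueError(f"no columns for conditions {cond_a!r}/{cond_b!r}")
    agg = pd.DataFrame.median if summary == "median" else pd.DataFrame.mean
    val_a = agg(matrix[cols_a], axis=1)
    val_b = agg(matrix[cols_b], axis=1)
    species = species.reindex(matrix.index)
    usable = val_a.notna() & val_b.notna() & species.isin(["human", "entrapment"])
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("ratio_deviation: %d proteins excluded (missing condition or species)", n_excluded)
    out = pd.DataFrame(
        {
            "species": species[usable],
            "observed_log2_ratio": (val_b - val_a)[usable],
        }
    )
    out["expected_log2_ratio"] = [
        expected_log2_ratio(design, cond_a, cond_b, sp) for sp in out["species"]
    ]
    out["deviation"] = out["observed_log2_ratio"] - out["expected_log2_ratio"]
    out.index.name = "protein_group"
    return out


def completeness_bins(matrix: pd.DataFrame, n_bins: int = 6) -> pd.Series:
    """Per-bin data completeness over abundance-ranked proteins.

    Proteins are ranked by median log2 intensity (descending, ties broken by
    identifier) and split into ``n_bins`` near-equal bins, remainder rows going
    to the top bins; completeness is the observed-cell fraction per bin.
    """
    n = matrix.shape[0]
    if n < n_bins:
        raise ValueError(f"{n} proteins cannot fill {n_bins} bins")
    order = (
        matrix.median(axis=1)
        .to_frame("med")
        .assign(protein=matrix.index)
        .sort_values(["med", "protein"], ascending=[False, True])
        .index
    )
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    fractions = []
    for i in range(n_bins):
        block = matrix.loc[order[bounds[i] : bounds[i + 1]]]
        fractions.append(float(block.notna().to_numpy().mean()))
    return pd.Series(fractions, index=pd.RangeIndex(1, n_bins + 1, name="bin"), name="completeness")


def sample_correlation(matrix: pd.DataFrame, min_pairwise: int = 10) -> pd.DataFrame:
    """Pearson correlation between sample columns on pairwise-complete log2 values.

    Pairs sharing fewer than ``min_pairwise`` proteins get NaN; the diagonal is 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("sample_correlation needs at least two samples")
    corr = matrix.corr(method="pearson", min_periods=min_pairwise)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores of a PCA restricted to fully observed proteins.

    Rows (proteins) are mean-centred; returns per-sample coordinates and the
    explained-variance fractions of the retained components.
    """
    from sklearn.decomposition import PCA

    complete = matrix.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("pca_scores needs at least two fully observed proteins")
    centred = complete.sub(complete.mean(axis=1), axis=0)
    n_components = min(n_components, min(centred.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centred.T.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=complete.columns, columns=cols), pca.explained_variance_ratio_


def dynamic_range(matrix: pd.DataFrame) -> float:
    """Orders of magnitude spanned by ranked median protein intensities."""
    if matrix.shape[0] < 1:
        raise ValueError("dynamic_range needs at least one protein")
    medians = matrix.median(axis=1).dropna()
    if medians.empty:
        raise ValueError("no observed protein medians")
    linear = np.exp2(medians)
    return float(np.log10(linear.max() / linear.min()))
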