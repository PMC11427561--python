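"""Differential expression, imputation, Z-scoring and protein co-variation analysis.

Operates on protein x cell log2 matrices with explicit missingness. Differential
expression is a two-sided Student's t-test (pooled variance by default, Welch by
flag) on log2 values with configurable significance thresholds (p < 0.05 and
|log2 fold change| > 0.95 by default). Co-variation is pairwise Pearson
correlation over observed values only, restricted to proteins seen in enough
cells and to pairs with enough shared observations, followed by hierarchical
clustering of correlation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "DeResult",
    "CovariationResult",
    "differential_expression",
    "impute_knn",
    "impute_min",
    "zscore_rows",
    "covariation_matrix",
    "cluster_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class CovariationResult:
    """Pairwise protein correlations across cells with their overlap counts."""

    correlation: pd.DataFrame
    pairwise_n: pd.DataFrame
    clusters: pd.Series | None = None

    @property
    def proteins(self) -> list[str]:
        return list(self.correlation.index)


#: columns of the differential-expression result table
DeResult = pd.DataFrame


def differential_expression(
    matrix: pd.DataFrame,
    groups: pd.Series | dict,
    control: str,
    treated: str,
    welch: bool = False,
    p_max: float = 0.05,
    min_abs_log2_fc: float = 0.95,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test per protein between two cell groups on log2 values.

    Returns a table with log2 fold change (treated minus control group means),
    p-value, per-group observation counts and a ``significant`` flag at the
    configured thresholds. Proteins with fewer than two observations in either
    group are skipped (their number is logged). ``bh_correct`` adds
    Benjamini-Hochberg adjusted q-values and flags on those instead.
    """
    groups = pd.Series(groups)
    cols_c = [c for c in matrix.columns if groups.get(c) == control]
    cols_t = [c for c in matrix.columns if groups.get(c) == treated]
    if len(cols_c) < 2 or len(cols_t) < 2:
        raise ValueError("both groups need at least two cells")
    a = matrix[cols_t].to_numpy(dtype=float)
    b = matrix[cols_c].to_numpy(dtype=float)
    n_t = (~np.isnan(a)).sum(axis=1)
    n_c = (~np.isnan(b)).sum(axis=1)
    testable = (n_t >= 2) & (n_c >= 2)
    skipped = int((~testable).sum())
    if skipped:
        log.info("differential_expression: %d proteins skipped (<2 values in a group)", skipped)
    with np.errstate(invalid="ignore"):
        res = stats.ttest_ind(
            a[testable], b[testable], axis=1, equal_var=not welch, nan_policy="omit"
        )
        fc = np.nanmean(a[testable], axis=1) - np.nanmean(b[testable], axis=1)
    out = pd.DataFrame(
        {
            "log2_fc": fc,
            "p_value": res.pvalue,
            "n_treated": n_t[testable],
            "n_control": n_c[testable],
        },
        index=matrix.index[testable],
    )
    out.index.name = "protein_group"
    if bh_correct:
        out["q_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
        crit = out["q_value"] < p_max
    else:
        crit = out["p_value"] < p_max
    out["significant"] = crit & (out["log2_fc"].abs() > min_abs_log2_fc)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(ranked)
    q[order] = np.minimum(ranked, 1.0)
    return q


def impute_knn(matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing cells from the k nearest protein rows.

    Distance between rows is the root-mean-square difference over their shared
    observed samples; a missing cell becomes the mean of the values of the k
    nearest rows that observe that sample. Observed cells are passed through
    bit-exactly; rows sharing no samples with any observing row stay missing
    (with a warning).
    """
    values = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    out = values.copy()
    n = values.shape[0]
    unimputable = 0
    for i in range(n):
        missing_cols = np.flatnonzero(~observed[i])
        if missing_cols.size == 0:
            continue
        # rmsd to every other row over shared samples
        shared = observed[i] & observed
        diffs = values[i] - values
        with np.errstate(invalid="ignore"):
            sq = np.where(shared, diffs**2, np.nan)
            counts = shared.sum(axis=1)
            rmsd = np.sqrt(np.nansum(sq, axis=1) / np.where(counts > 0, counts, np.nan))
        rmsd[i] = np.nan
        for j in missing_cols:
            candidates = np.flatnonzero(observed[:, j] & ~np.isnan(rmsd))
            if candidates.size == 0:
                unimputable += 1
                continue
            nearest = candidates[np.argsort(rmsd[candidates], kind="stable")[:k]]
            out[i, j] = values[nearest, j].mean()
    if unimputable:
        log.warning("impute_knn: %d cells left missing (no overlapping neighbour)", unimputable)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def impute_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace every missing cell by the lowest observed value of the dataset."""
    observed = matrix.stack()
    if observed.empty:
        raise ValueError("cannot impute an all-missing matrix")
    return matrix.fillna(float(observed.min()))


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row Z-score with median centring: (x - row median) / row sd (n-1).

    Rows with zero variance (or <2 values) become all-NaN with a warning.
    """
    med = matrix.median(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    degenerate = (sd == 0) | sd.isna()
    if degenerate.any():
        log.warning("zscore_rows: %d rows with zero variance set to NaN", int(degenerate.sum()))
    sd = sd.mask(degenerate)
    return matrix.sub(med, axis=0).div(sd, axis=0)


def covariation_matrix(
    matrix: pd.DataFrame,
    min_cells: int = 20,
    min_pairwise: int = 20,
) -> CovariationResult:
    """Protein-protein Pearson correlation across cells, observed values only.

    Restricts to proteins observed in at least ``min_cells`` cells; pairs
    sharing fewer than ``min_pairwise`` cells are left undefined. Run this on
    unimputed data — imputation would fabricate co-variation.
    """
    qualifying = matrix.index[matrix.notna().sum(axis=1) >= min_cells]
    if len(qualifying) < 2:
        raise ValueError(f"fewer than two proteins observed in >= {min_cells} cells")
    sub = matrix.loc[qualifying]
    corr = sub.T.corr(method="pearson", min_periods=min_pairwise)
    observed = sub.notna().astype(int)
    pairwise_n = observed @ observed.T
    corr = corr.mask(pairwise_n < min_pairwise)
    np.fill_diagonal(corr.values, 1.0)
    return CovariationResult(correlation=corr, pairwise_n=pairwise_n)


def cluster_correlation(
    result: CovariationResult,
    n_clusters: int = 2,
    linkage_method: str = "average",
) -> tuple[pd.Series, list[str]]:
    """Hierarchical clustering of proteins on their correlation profiles.

    Rows of the correlation matrix are compared by Euclidean distance (undefined
    cells count as 0, the neutral correlation, for the distance computation
    only) and clustered agglomeratively; the tree is cut at ``n_clusters``.
    Returns cluster labels and the dendrogram leaf order for heatmaps.
    """
    corr = result.correlation
    if n_clusters > corr.shape[0]:
        raise ValueError(f"cannot cut {corr.shape[0]} proteins into {n_clusters} clusters")
    profiles = corr.fillna(0.0).to_numpy()
    link = hierarchy.linkage(pdist(profiles, metric="euclidean"), method=linkage_method)
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    clusters = pd.Series(labels, index=corr.index, name="cluster")
    result.clusters = clusters
    return clusters, [corr.index[i] for i in order]
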