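"""Allelic-ratio matrices and clonal-stability analysis.

The allelic profile of a clone — the vector of per-feature B6 fractions on the
0 (pure Cast) to 1 (pure B6) scale — is stable across divisions and passages
and distinct between clones, while a pool of many clones sits near the
balanced centre.  This module builds the feature x sample ratio matrix (NaN
where allele-informative depth is below threshold), projects samples by PCA
with a deterministic sign convention, clusters them hierarchically, exports
the dendrogram as Newick, renders the red (Cast) to blue (B6) heatmap with
white for missing entries, and cross-tabulates ATAC promoter calls against
RNA calls for the accessibility/transcription concordance test.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .allelic_assignment import ratio_series

logger = logging.getLogger(__name__)

HEATMAP_MIN_DEPTH = 10  # ratio-heatmap whiteout threshold


def build_ratio_matrix(
    tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
    min_depth: int = HEATMAP_MIN_DEPTH,
) -> pd.DataFrame:
    """Feature x sample matrix of allelic ratios.

    ``tables`` is either a mapping sample id -> count table (feature_id, b6,
    cast) or one long table with a sample column.  Entries with combined depth
    below ``min_depth`` are NaN; features that are NaN in every sample are
    dropped (logged).
    """
    if isinstance(tables, pd.DataFrame):
        split = {str(s): g for s, g in tables.groupby("sample", sort=True)}
        if len(split) != tables["sample"].nunique():
            raise ValueError("duplicate sample ids")
        tables = split
    cols = {}
    for sample, tbl in tables.items():
        if sample in cols:
            raise ValueError(f"duplicate sample id {sample!r}")
        if tbl["feature_id"].duplicated().any():
            raise ValueError(f"sample {sample!r}: duplicate feature entries")
        cols[sample] = pd.Series(
            ratio_series(tbl, min_depth=min_depth).to_numpy(),
            index=pd.Index(tbl["feature_id"], name="feature_id"),
        )
    matrix = pd.DataFrame(cols)
    all_na = matrix.isna().all(axis=1)
    if all_na.any():
        logger.info("dropping %d features with no depth-sufficient sample", int(all_na.sum()))
        matrix = matrix.loc[~all_na]
    return matrix


def _complete_case(matrix: pd.DataFrame, na_policy: str) -> pd.DataFrame:
    if na_policy == "complete":
        kept = matrix.dropna(axis=0)
        dropped = len(matrix) - len(kept)
        if dropped:
            logger.info("complete-case filter dropped %d features", dropped)
        return kept
    if na_policy == "mean":
        return matrix.apply(lambda row: row.fillna(row.mean()), axis=1)
    raise ValueError("na_policy must be 'complete' or 'mean'")


@dataclass(frozen=True)
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    n_features: int


def pca_profiles(
    matrix: pd.DataFrame, na_policy: str = "complete", n_components: int | None = None
) -> PcaResult:
    """PCA of samples over their allelic-ratio profiles.

    Samples (columns of the matrix) are the observations.  Feature rows with
    missing entries are handled per ``na_policy`` ('complete' drops them,
    'mean' imputes the feature's row mean).  Deterministic output: plain SVD of
    the feature-centred data with the sign of each component fixed so its
    largest-magnitude loading is positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    filled = _complete_case(matrix, na_policy)
    if filled.empty:
        raise ValueError("no features left after missing-data filtering")
    x = filled.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| positive per component
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    coords = u * s
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = n_components or coords.shape[1]
    coords = coords[:, :k]
    names = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.columns, columns=names),
        explained_variance_ratio=evr[:k],
        n_features=filled.shape[0],
    )


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    labels: list
    newick: str


def _linkage_to_newick(z: np.ndarray, labels: list) -> str:
    tree = hierarchy.to_tree(z)

    def rec(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cluster_profiles(
    matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
    na_policy: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of samples on their ratio profiles.

    Euclidean distance and average linkage by default; on well-separated
    clones, replicate pairs merge before any cross-clone merge.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    filled = _complete_case(matrix, na_policy)
    if filled.empty:
        raise ValueError("no features left after missing-data filtering")
    x = filled.to_numpy(dtype=float).T
    z = hierarchy.linkage(x, method=method, metric=metric)
    labels = list(matrix.columns)
    return ClusterResult(linkage=z, labels=labels, newick=_linkage_to_newick(z, labels))


def cut_clusters(result: ClusterResult, n_clusters: int) -> pd.Series:
    """Flat cluster membership from the dendrogram (maxclust criterion)."""
    flat = hierarchy.fcluster(result.linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(flat, index=result.labels, name="cluster")


def promoter_concordance(
    atac_calls: pd.Series, rna_calls: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """Concordance of allelic chromatin accessibility with allelic transcription.

    Cross-tabulates the {mono_b6, mono_cast, biallelic} call of ATAC promoter
    peaks against the call of the corresponding transcripts over shared feature
    ids (insufficient calls excluded) and applies the Pearson chi-square test
    of independence.  Returns (3x3 table, statistic, p).
    """
    cats = ["mono_b6", "mono_cast", "biallelic"]
    shared = atac_calls.index.intersection(rna_calls.index)
    a = atac_calls.loc[shared]
    r = rna_calls.loc[shared]
    keep = a.isin(cats) & r.isin(cats)
    a, r = a[keep], r[keep]
    if len(a) == 0:
        raise ValueError("no shared callable features")
    table = pd.crosstab(a, r).reindex(index=cats, columns=cats, fill_value=0)
    table.index.name, table.columns.name = "atac", "rna"
    nonzero_rows = table.sum(axis=1) > 0
    nonzero_cols = table.sum(axis=0) > 0
    trimmed = table.loc[nonzero_rows, nonzero_cols]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        raise ValueError("contingency table is degenerate (fewer than 2x2 informative cells)")
    stat, p, _, _ = stats.chi2_contingency(trimmed.to_numpy(), correction=False)
    return table, float(stat), float(p)


def replicate_stability(
    coords: pd.DataFrame, replicate_of: Mapping[str, str], n_components: int = 2
) -> bool:
    """True when each sample's nearest neighbour in PC space is its own replicate."""
    x = coords.iloc[:, :n_components].to_numpy(dtype=float)
    labels = list(coords.index)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    for i, lab in enumerate(labels):
        nn = labels[int(np.argmin(d[i]))]
        if replicate_of[lab] != replicate_of[nn]:
            return False
    return True


def plot_ratio_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the ratio matrix: linear red (0, pure Cast) to blue (1, pure B6),
    white for entries under the depth threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = matplotlib.colormaps["bwr_r"].copy()
    cmap.set_bad("white")
    data = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * matrix.shape[1] + 2), 6))
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]), labels=list(matrix.columns), rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{matrix.shape[0]} features")
    fig.colorbar(im, ax=ax, label="allelic ratio (0 = Cast, 1 = B6)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "build_ratio_matrix",
    "pca_profiles",
    "cluster_profiles",
    "cut_clusters",
    "promoter_concordance",
    "replicate_stability",
    "plot_ratio_heatmap",
    "PcaResult",
    "ClusterResult",
    "HEATMAP_MIN_DEPTH",
]
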