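"""Standardization and hierarchical clustering of peak-area profiles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import PeakTable

__all__ = [
    "StandardizedMatrix",
    "ClusterResult",
    "standardize",
    "hca",
    "cut_tree",
    "leaf_order",
    "export_heatmap",
]


@dataclass
class StandardizedMatrix:
    """Column z-scores (sample sd) with the original means/sds retained."""

    z: pd.DataFrame
    column_means: pd.Series
    column_sds: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.index)


def standardize(peaks: PeakTable) -> StandardizedMatrix:
    """Z-score each analyte column with the sample (n-1) standard deviation."""
    df = peaks.areas
    if len(df) < 2:
        raise ValueError("need at least two samples")
    if df.isna().any().any():
        raise ValueError("missing cells: impute or drop before standardizing")
    sds = df.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    means = df.mean()
    return StandardizedMatrix(z=(df - means) / sds, column_means=means,
                              column_sds=sds)


@dataclass
class ClusterResult:
    """Agglomerative merge tree over samples."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    sample_ids: list[str]
    method: str

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if self.method == "ward" and np.any(np.diff(heights) < -1e-9):
            raise ValueError("ward merge heights must be non-decreasing")


def hca(z: StandardizedMatrix, distance: str = "euclidean",
        linkage: str = "ward") -> ClusterResult:
    """Agglomerative clustering of standardized profiles.

    Euclidean distance on z-scores; linkage one of ward (default), average
    or complete. Tie-breaking follows the deterministic lowest-index order
    of the condensed distance matrix, so identical inputs give identical
    trees.
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValueError("linkage must be ward, average or complete")
    if distance != "euclidean":
        raise ValueError("only euclidean distance is supported")
    d = pdist(z.z.to_numpy(dtype=float), metric=distance)
    lm = hierarchy.linkage(d, method=linkage)
    return ClusterResult(linkage_matrix=lm, sample_ids=z.sample_ids,
                         method=linkage)


def cut_tree(result: ClusterResult, k: int) -> pd.Series:
    """Partition into k groups by removing the k-1 highest merges."""
    n = len(result.sample_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    labels = hierarchy.fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    return pd.Series(labels, index=result.sample_ids, name="group")


def leaf_order(result: ClusterResult) -> list[str]:
    order = hierarchy.leaves_list(result.linkage_matrix)
    return [result.sample_ids[i] for i in order]


def export_heatmap(z: StandardizedMatrix, result: ClusterResult,
                   image_path: str | Path,
                   matrix_path: str | Path | None = None) -> list[str]:
    """Write a clustered heatmap image plus the leaf-ordered matrix as CSV.

    Returns the dendrogram leaf order used for the rows.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = leaf_order(result)
    ordered = z.z.loc[order]
    fig, (ax_d, ax_h) = plt.subplots(
        1, 2, figsize=(8, 6), gridspec_kw={"width_ratios": [1, 3]})
    hierarchy.dendrogram(result.linkage_matrix, orientation="left",
                         labels=z.sample_ids, ax=ax_d, color_threshold=0)
    ax_d.invert_yaxis()
    im = ax_h.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax_h.set_yticks(range(len(order)), order)
    ax_h.set_xticks(range(len(ordered.columns)), ordered.columns,
                    rotation=60, ha="right", fontsize=7)
    fig.colorbar(im, ax=ax_h, label="z-score")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)
    if matrix_path is not None:
        ordered.to_csv(matrix_path, index_label="sample")
    return order
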