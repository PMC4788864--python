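"""Tissue-expression atlas processing: filter, transform, cluster.

Mirrors the common heat-map workflow for an FPKM genes-by-tissues matrix:
drop genes with zero abundance in every tissue, log10-transform with a
pseudocount, mean-centre each gene row, then cluster genes by average
linkage (UPGMA) on Euclidean distance. The dendrogram and leaf order are
exported as text (Newick + ordered TSV) rather than drawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def drop_all_zero(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove rows that are zero in every column; report what was dropped."""
    zero_mask = (matrix == 0).all(axis=1)
    dropped = matrix.index[zero_mask].tolist()
    retained = matrix.loc[~zero_mask]
    if retained.empty:
        warnings.warn("all rows are zero; retained matrix is empty", stacklevel=2)
    return retained, dropped


def transform_center(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log10(v + pseudocount), then subtract each gene-row's mean."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    logged = np.log10(values + pseudocount)
    centred = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusteredMatrix:
    data: pd.DataFrame          # transformed values, rows in leaf order
    leaf_order: list[str]
    linkage: np.ndarray         # scipy linkage matrix over the input row order
    input_index: list[str]


def hcluster(
    transformed: pd.DataFrame,
    *,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusteredMatrix:
    """Agglomerative clustering of gene rows; deterministic leaf order.

    scipy breaks equal-height merge ties by cluster creation order, which
    is fixed given the input row order; row order in turn is sorted here by
    gene id so the result is permutation-invariant.
    """
    if transformed.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    ordered = transformed.sort_index(kind="stable")
    distances = pdist(ordered.to_numpy(), metric=metric)
    linkage = hierarchy.linkage(distances, method=method)
    leaves = hierarchy.leaves_list(linkage)
    leaf_order = [ordered.index[i] for i in leaves]
    return ClusteredMatrix(
        data=ordered.iloc[leaves],
        leaf_order=leaf_order,
        linkage=linkage,
        input_index=ordered.index.tolist(),
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths
    derived from merge heights (each child branch spans parent minus child
    height)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    subtrees = {i: labels[i] for i in range(n)}
    for k, (left, right, height, _) in enumerate(linkage):
        left, right = int(left), int(right)
        node = n + k
        bl_left = height - heights[left]
        bl_right = height - heights[right]
        subtrees[node] = (
            f"({subtrees[left]}:{bl_left:.6g},{subtrees[right]}:{bl_right:.6g})"
        )
        heights[node] = height
    return subtrees[n + len(linkage) - 1] + ";"


def process_atlas(
    matrix: pd.DataFrame,
    *,
    pseudocount: float = 1.0,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[ClusteredMatrix, list[str]]:
    """Full stage: drop all-zero rows, transform + centre, cluster."""
    retained, dropped = drop_all_zero(matrix)
    transformed = transform_center(retained, pseudocount)
    clustered = hcluster(transformed, metric=metric, method=method)
    return clustered, dropped


def write_clustered(clustered: ClusteredMatrix, out_dir: str | Path, stem: str = "atlas") -> None:
    out_dir = Path(out_dir)
    clustered.data.to_csv(out_dir / f"{stem}_ordered.tsv", sep="\t", index_label="gene_id")
    newick = linkage_to_newick(clustered.linkage, clustered.input_index)
    (out_dir / f"{stem}_dendrogram.nwk").write_text(newick + "\n")
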