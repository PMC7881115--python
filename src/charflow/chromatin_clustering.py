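"""Accessibility-module clustering of differential ChARs.

Selected ChARs are extended 500 bp up- and downstream of their centre; mean
per-bp fragment coverage in the window is computed per replicate, normalized
by uniquely mapped reads (x 10^6), scaled 0-1 per ChAR across replicates, and
hierarchically clustered (complete linkage on Euclidean distances). The
dendrogram is cut into k flat modules; k defaults to 5 but a silhouette
summary over k = 2..20 is provided to support the choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from charflow.region_algebra import ChAR, TaggedRead

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 500


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # char_id -> module label (1..k)
    k: int
    linkage: np.ndarray  # scipy linkage matrix
    leaf_ids: list[str]

    def members(self, label: int) -> list[str]:
        return [cid for cid, lab in self.labels.items() if lab == label]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with char ids as leaves."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def build_coverage_matrix(
    chars_selected: list[ChAR],
    fragments_per_replicate: dict[str, list[TaggedRead]],
    library_sizes: dict[str, int] | None = None,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Mean per-bp coverage per (ChAR window, replicate), library-normalized.

    The window is ``[center - flank, center + flank)``, clipped at the
    chromosome start (with a warning). Coverage is the per-bp fragment pileup
    averaged over the window, divided by the replicate's library size (total
    fragments when not given) and multiplied by 10^6.
    """
    sample_ids = list(fragments_per_replicate)
    if library_sizes is None:
        library_sizes = {s: len(fragments_per_replicate[s]) for s in sample_ids}
    trees: dict[str, dict[str, IntervalTree]] = {}
    for s, frags in fragments_per_replicate.items():
        per_chrom: dict[str, IntervalTree] = {}
        for f in frags:
            per_chrom.setdefault(f.interval.chrom, IntervalTree()).addi(
                f.interval.start, f.interval.end
            )
        trees[s] = per_chrom

    mat = np.zeros((len(chars_selected), len(sample_ids)))
    for i, ch in enumerate(chars_selected):
        c = ch.interval.center
        start, end = c - flank, c + flank
        if start < 0:
            logger.warning("coverage window for %s clipped at chromosome start", ch.id)
            start = 0
        width = end - start
        for j, s in enumerate(sample_ids):
            tree = trees[s].get(ch.interval.chrom)
            if tree is None:
                continue
            total_bp = sum(
                min(end, hit.end) - max(start, hit.begin)
                for hit in tree.overlap(start, end)
            )
            mat[i, j] = total_bp / width / library_sizes[s] * 1e6
    return pd.DataFrame(mat, index=[ch.id for ch in chars_selected], columns=sample_ids)


def scale_rows_unit(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to [0, 1]; constant rows become all-zero (flagged)."""
    vals = matrix.to_numpy(dtype=float)
    mins = vals.min(axis=1, keepdims=True)
    maxs = vals.max(axis=1, keepdims=True)
    span = maxs - mins
    const = (span == 0).ravel()
    if const.any():
        logger.warning("%d constant rows scaled to all zeros", int(const.sum()))
    span[span == 0] = 1.0
    scaled = (vals - mins) / span
    scaled[const, :] = 0.0
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def hierarchical_modules(
    scaled_matrix: pd.DataFrame, k: int, method: str = "complete"
) -> ClusterAssignment:
    """Cut a complete-linkage dendrogram of the scaled rows into k modules.

    Module labels 1..k are ordered by descending module size, ties broken by
    the position of the module's first member in the input row order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = scaled_matrix.shape[0]
    if n < k:
        raise ValueError(f"cannot cut {n} rows into {k} clusters")
    # row-order invariance: cluster rows in a canonical (lexicographic) order
    order = np.lexsort(scaled_matrix.to_numpy().T[::-1])
    canon = scaled_matrix.iloc[order]
    z = hierarchy.linkage(canon.to_numpy(), method=method, metric="euclidean")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # back to input order
    raw_in_input = np.empty(n, dtype=int)
    raw_in_input[order] = raw
    # stable relabel: descending size, then first occurrence in input order
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for pos, lab in enumerate(raw_in_input):
        sizes[lab] = sizes.get(lab, 0) + 1
        first.setdefault(lab, pos)
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], first[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(ranked)}
    labels = {
        cid: remap[lab] for cid, lab in zip(scaled_matrix.index, raw_in_input)
    }
    return ClusterAssignment(
        labels=labels, k=k, linkage=z, leaf_ids=list(canon.index)
    )


def silhouette_summary(
    scaled_matrix: pd.DataFrame, k_range: range = range(2, 21), method: str = "complete"
) -> pd.DataFrame:
    """Mean silhouette width for each candidate k (supports choosing k)."""
    rows = []
    x = scaled_matrix.to_numpy()
    z = hierarchy.linkage(x, method=method, metric="euclidean")
    for k in k_range:
        if k >= len(x):
            break
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        rows.append({"k": k, "silhouette": silhouette_score(x, labels)})
    return pd.DataFrame(rows)


def refset_zscore_profile(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-scores across samples (ddof=1); constant rows -> zeros."""
    if counts.shape[1] < 2:
        raise ValueError("z-scores require >= 2 samples")
    vals = counts.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        logger.warning("%d constant rows in z-score profile set to zeros", int(const.sum()))
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    z[const, :] = 0.0
    return pd.DataFrame(z, index=counts.index, columns=counts.columns)
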