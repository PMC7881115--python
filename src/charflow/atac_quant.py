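"""Fragment counting, ENCODE library-complexity QC, normalization, MDS.

Library complexity follows the ENCODE definitions: NRF = distinct insertion
positions / total reads, PBC1 = positions seen exactly once / distinct
positions, PBC2 = positions seen exactly once / positions seen exactly twice.
FRiP is the fraction of reads overlapping any called peak by >= 1 bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from charflow.intervals import GenomicInterval
from charflow.region_algebra import ChAR, TaggedRead

logger = logging.getLogger(__name__)

LOGCPM_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer counts (features x samples) with library sizes and metadata.

    ``library_sizes`` are total uniquely mapped fragments per sample, which may
    exceed the column sum when fragments fall outside all features.
    ``sample_meta`` maps sample id -> (condition label, replicate index).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (features, samples), non-negative ints
    library_sizes: np.ndarray  # shape (samples,)
    sample_meta: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match feature/sample ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            library_sizes=self.library_sizes[idx],
            sample_meta={s: self.sample_meta[s] for s in sample_ids if s in self.sample_meta},
        )


@dataclass
class QCReport:
    total_reads: int
    distinct_positions: int
    nrf: float
    pbc1: float
    pbc2: float
    frip: float

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "distinct_positions": self.distinct_positions,
            "NRF": self.nrf,
            "PBC1": self.pbc1,
            "PBC2": None if math.isinf(self.pbc2) else self.pbc2,
            "FRiP": self.frip,
        }


def count_fragments_in_regions(
    fragments: list[TaggedRead],
    regions: list[ChAR],
    multi_overlap: str = "all",
) -> tuple[np.ndarray, int]:
    """Count fragments per region (>= 1 bp overlap) for one sample.

    With ``multi_overlap="all"`` (default) a fragment spanning several regions
    increments each of them; with ``"none"`` multi-region fragments are
    discarded. Returns the per-region count vector and the library size
    (total fragments, including off-region ones).
    """
    if multi_overlap not in ("all", "none"):
        raise ValueError(f"unknown multi_overlap mode {multi_overlap!r}")
    trees: dict[str, IntervalTree] = {}
    for i, ch in enumerate(regions):
        trees.setdefault(ch.interval.chrom, IntervalTree()).addi(
            ch.interval.start, ch.interval.end, i
        )
    counts = np.zeros(len(regions), dtype=np.int64)
    for frag in fragments:
        iv = frag.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        if not hits:
            continue
        if multi_overlap == "none" and len(hits) > 1:
            continue
        for i in hits:
            counts[i] += 1
    return counts, len(fragments)


def library_qc(
    reads: list[TaggedRead], peaks: list[GenomicInterval]
) -> QCReport:
    """ENCODE library-complexity ratios plus FRiP for one sample.

    An insertion position is the strand-aware 5' coordinate of a read:
    ``(chrom, start, strand)`` on +, ``(chrom, end, strand)`` on -.
    """
    if not reads:
        raise ValueError("library_qc requires at least one read")
    pos_counts: dict[tuple, int] = {}
    for r in reads:
        iv = r.interval
        pos = iv.end if iv.strand == "-" else iv.start
        key = (iv.chrom, pos, iv.strand)
        pos_counts[key] = pos_counts.get(key, 0) + 1
    total = len(reads)
    distinct = len(pos_counts)
    if distinct == 0:  # pragma: no cover - impossible with reads present
        raise ValueError("no distinct positions")
    singletons = sum(1 for v in pos_counts.values() if v == 1)
    doubletons = sum(1 for v in pos_counts.values() if v == 2)
    if doubletons == 0:
        logger.warning("no two-read positions; PBC2 reported as +inf")
        pbc2 = math.inf
    else:
        pbc2 = singletons / doubletons

    peak_trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        peak_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    in_peaks = 0
    for r in reads:
        iv = r.interval
        tree = peak_trees.get(iv.chrom)
        if tree and tree.overlap(iv.start, iv.end):
            in_peaks += 1

    return QCReport(
        total_reads=total,
        distinct_positions=distinct,
        nrf=distinct / total,
        pbc1=singletons / distinct,
        pbc2=pbc2,
        frip=in_peaks / total,
    )


def normalize_counts(
    matrix: CountMatrix,
    mode: str,
    feature_lengths: np.ndarray | None = None,
    pseudocount: float = LOGCPM_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Normalize counts to CPM, logCPM (log2(CPM + pseudocount)) or RPKM.

    RPKM divides CPM by feature length in kb and requires ``feature_lengths``
    (bp, aligned with ``matrix.feature_ids``).
    """
    if (matrix.library_sizes <= 0).any():
        raise ValueError("zero or negative library size")
    cpm = matrix.counts / matrix.library_sizes[None, :] * 1e6
    if mode == "CPM":
        vals = cpm
    elif mode == "logCPM":
        vals = np.log2(cpm + pseudocount)
    elif mode == "RPKM":
        if feature_lengths is None:
            raise ValueError("RPKM requires feature lengths")
        lengths_kb = np.asarray(feature_lengths, dtype=float) / 1000.0
        if (lengths_kb <= 0).any():
            raise ValueError("non-positive feature length")
        vals = cpm / lengths_kb[:, None]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return pd.DataFrame(vals, index=matrix.feature_ids, columns=matrix.sample_ids)


def mds_coordinates(
    logcpm: pd.DataFrame, top_n: int = 500
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise RMS (root-mean-square) distances over the top-variance features
    and a 2-D classical-MDS embedding.

    d(i,j) = sqrt(mean over selected features of (x_i - x_j)^2). Distances are
    exact; coordinates are defined up to rotation/reflection.
    """
    if logcpm.shape[1] < 2:
        raise ValueError("MDS requires at least 2 samples")
    variances = logcpm.var(axis=1, ddof=1)
    n_sel = min(top_n, logcpm.shape[0])
    selected = variances.sort_values(ascending=False, kind="stable").index[:n_sel]
    x = logcpm.loc[selected].to_numpy().T  # samples x features
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).mean(axis=2))
    dist_df = pd.DataFrame(dist, index=logcpm.columns, columns=logcpm.columns)

    # classical (Torgerson) MDS: eigendecomposition of the double-centred
    # squared-distance matrix
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ndim = min(2, n - 1)
    coords = np.zeros((n, 2))
    for d in range(ndim):
        lam = max(evals[d], 0.0)
        coords[:, d] = evecs[:, d] * np.sqrt(lam)
    coords_df = pd.DataFrame(coords, index=logcpm.columns, columns=["dim1", "dim2"])
    return coords_df, dist_df
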