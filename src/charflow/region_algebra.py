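"""Region arithmetic for ChARs (chromatin accessible regions).

Covers Tn5 insertion-shift correction of reads, pooling and merging of peak
calls across conditions, genomic-context annotation with a strict
promoter > exon > intron > intergenic priority, nearest-gene assignment with
a distance cap, TCF-1-bound gene flagging, and overlap against reference
peaksets (e.g. exhaustion- or effector-associated regions).

Merging follows the rule used to build the consensus region set: two pooled
regions overlapping by at least 50% of the width of the larger one are
replaced by their intersection; regions overlapping less (or not at all) are
kept unchanged. Because the stated rule is pairwise, chains of overlaps are
resolved by sweeping the coordinate-sorted pool left to right against the
running region and iterating to a fixpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from charflow.intervals import GenomicInterval
from charflow.genome_annotation import UniqueGeneModel

logger = logging.getLogger(__name__)

ANNOTATION_PRIORITY = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class TaggedRead:
    """A sequencing read/fragment with strand, as a half-open interval."""

    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class ChAR:
    """Chromatin accessible region with provenance and downstream annotations."""

    interval: GenomicInterval
    id: str
    source_peaks: list[str] = field(default_factory=list)
    annotation: str | None = None
    assigned_gene: str | None = None
    distance_to_gene: int | None = None


def shift_tn5(reads: list[TaggedRead]) -> list[TaggedRead]:
    """Shift read coordinates +4 bp (+ strand) / -5 bp (- strand) to centre
    them on the Tn5 insertion site (correcting the 9-bp duplication).

    Width is preserved; a shift that would push the start below 0 is clipped
    to 0 with a warning.
    """
    out: list[TaggedRead] = []
    for read in reads:
        iv = read.interval
        if iv.strand == "+":
            shift = 4
        elif iv.strand == "-":
            shift = -5
        else:
            raise ValueError(f"read {iv} has no strand; Tn5 shift requires one")
        start, end = iv.start + shift, iv.end + shift
        if start < 0:
            logger.warning("Tn5 shift clipped read %s at chromosome start", iv)
            end = end - start
            start = 0
        out.append(TaggedRead(GenomicInterval(iv.chrom, start, end, iv.strand)))
    return out


def _merge_rule(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True when the pair must be merged: overlap >= 50% of the larger width."""
    ov = a.overlap_len(b)
    return ov > 0 and ov >= 0.5 * max(a.width, b.width)


def _sweep_once(
    sorted_regions: list[GenomicInterval], mode: str
) -> tuple[list[GenomicInterval], bool]:
    out: list[GenomicInterval] = []
    changed = False
    cur = sorted_regions[0]
    for nxt in sorted_regions[1:]:
        if cur == nxt:
            changed = True  # exact duplicate collapses silently
            continue
        if _merge_rule(cur, nxt):
            if mode == "intersection":
                cur = cur.intersection(nxt)
            else:
                cur = GenomicInterval(
                    cur.chrom, min(cur.start, nxt.start), max(cur.end, nxt.end)
                )
            changed = True
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out, changed


def pool_and_merge(
    peaksets: list[list[GenomicInterval]], merge_mode: str = "intersection"
) -> list[ChAR]:
    """Pool peak calls from all inputs and merge by the 50%-of-larger-width rule.

    Parameters
    ----------
    peaksets : per-condition (or per-sample) peak interval lists.
    merge_mode : ``"intersection"`` (qualifying pairs replaced by their
        overlap, the default) or ``"union"``.

    Returns ChARs with deterministic ids ``chrom:start-end``, sorted by
    coordinate. Mixed chromosome naming schemes (``chr1`` vs ``1``) raise.
    """
    if merge_mode not in ("intersection", "union"):
        raise ValueError(f"unknown merge_mode {merge_mode!r}")
    pooled = [iv for ps in peaksets for iv in ps]
    if not pooled:
        return []
    chroms = {iv.chrom for iv in pooled}
    prefixed = {c for c in chroms if c.startswith("chr")}
    if prefixed and prefixed != chroms:
        raise ValueError(
            "mixed chromosome naming schemes in pooled peaks: "
            f"{sorted(prefixed)} vs {sorted(chroms - prefixed)}"
        )
    regions = sorted(
        {GenomicInterval(iv.chrom, iv.start, iv.end) for iv in pooled},
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    while True:
        regions, changed = _sweep_once(regions, merge_mode)
        regions = sorted(set(regions), key=lambda iv: (iv.chrom, iv.start, iv.end))
        if not changed:
            break
    return [ChAR(interval=iv, id=str(iv)) for iv in regions]


def _build_trees(intervals_with_payload):
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals_with_payload:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def annotate_regions(
    chars: list[ChAR], gene_models: dict[str, UniqueGeneModel]
) -> list[ChAR]:
    """Assign each ChAR exactly one genomic-context label by strict priority.

    A ChAR overlapping any promoter by >= 1 bp is ``promoter``; otherwise an
    exon overlap makes it ``exon``; otherwise overlap with a gene span
    (i.e. intronic sequence) makes it ``intron``; the rest are ``intergenic``.
    """
    promoter_trees = _build_trees((m.promoter, gid) for gid, m in gene_models.items())
    exon_trees = _build_trees(
        (e, gid) for gid, m in gene_models.items() for e in m.exons
    )
    span_trees = _build_trees((m.span, gid) for gid, m in gene_models.items())

    def hits(trees, iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return bool(tree and tree.overlap(iv.start, iv.end))

    for ch in chars:
        iv = ch.interval
        if hits(promoter_trees, iv):
            ch.annotation = "promoter"
        elif hits(exon_trees, iv):
            ch.annotation = "exon"
        elif hits(span_trees, iv):
            ch.annotation = "intron"
        else:
            ch.annotation = "intergenic"
    return chars


def annotation_fractions(chars: list[ChAR]) -> dict[str, float]:
    n = len(chars)
    return {
        cat: (sum(1 for c in chars if c.annotation == cat) / n if n else 0.0)
        for cat in ANNOTATION_PRIORITY
    }


def assign_nearest_gene(
    chars: list[ChAR],
    gene_models: dict[str, UniqueGeneModel],
    max_distance: int = 50_000,
) -> list[ChAR]:
    """Assign each ChAR to an overlapping gene (distance 0) or, failing that,
    to the closest gene span within ``max_distance`` bp (edge-to-edge gap).

    Ties on distance are broken by lexicographic gene_id for determinism.
    Overlap ties are broken the same way.
    """
    span_trees = _build_trees((m.span, gid) for gid, m in gene_models.items())
    # sorted span lists per chromosome for the gap scan
    spans_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, m in gene_models.items():
        spans_by_chrom.setdefault(m.chrom, []).append((m.span.start, m.span.end, gid))
    for lst in spans_by_chrom.values():
        lst.sort()

    for ch in chars:
        iv = ch.interval
        tree = span_trees.get(iv.chrom)
        overlapping = sorted(hit.data for hit in tree.overlap(iv.start, iv.end)) if tree else []
        if overlapping:
            ch.assigned_gene = overlapping[0]
            ch.distance_to_gene = 0
            continue
        best: tuple[int, str] | None = None
        for start, end, gid in spans_by_chrom.get(iv.chrom, []):
            if end <= iv.start:
                gap = iv.start - end
            elif start >= iv.end:
                gap = start - iv.end
            else:  # pragma: no cover - overlap handled above
                gap = 0
            if gap <= max_distance and (best is None or (gap, gid) < best):
                best = (gap, gid)
        if best is not None:
            ch.distance_to_gene, ch.assigned_gene = best
        else:
            ch.assigned_gene = None
            ch.distance_to_gene = None
    return chars


def flag_tcf1_bound(
    gene_models: dict[str, UniqueGeneModel],
    binding_sites: list[GenomicInterval],
    window: int = 10_000,
) -> dict[str, bool]:
    """Flag genes with a TCF-1 binding site within ``window`` bp of the gene
    span (upstream, downstream, or inside)."""
    site_trees = _build_trees((iv, i) for i, iv in enumerate(binding_sites))
    flags: dict[str, bool] = {}
    for gid, m in gene_models.items():
        tree = site_trees.get(m.chrom)
        lo = max(0, m.span.start - window)
        hi = m.span.end + window
        flags[gid] = bool(tree and tree.overlap(lo, hi))
    return flags


def overlap_refset(
    chars: list[ChAR], refset: list[GenomicInterval]
) -> dict[str, list[GenomicInterval]]:
    """Map each ChAR id to the reference peaks it overlaps by >= 1 bp
    (many-to-many)."""
    if not refset:
        raise ValueError("reference peakset is empty")
    trees = _build_trees((iv, iv) for iv in refset)
    out: dict[str, list[GenomicInterval]] = {}
    for ch in chars:
        tree = trees.get(ch.interval.chrom)
        hits = (
            sorted((h.data for h in tree.overlap(ch.interval.start, ch.interval.end)),
                   key=lambda iv: (iv.chrom, iv.start, iv.end))
            if tree
            else []
        )
        if hits:
            out[ch.id] = hits
    return out
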