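"""Transcript annotation parsing and the unique gene model.

The unique gene model collapses all annotated exons of all protein-coding
isoforms of a gene into one merged-exon structure, as if they came from a
single RNA molecule. The promoter is a 3000-bp window around the model's TSS:
2000 bp upstream and 1000 bp downstream of transcription start, oriented by
strand (an absolute-coordinate mode is available via ``strand_aware=False``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from charflow.intervals import GenomicInterval, merge_overlapping

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 1000

_ATTR_RE = re.compile(r'(\S+) "([^"]*)"')


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: its gene, biotype, strand and exon intervals."""

    gene_id: str
    transcript_id: str
    biotype: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]


@dataclass(frozen=True)
class UniqueGeneModel:
    """Per-gene merged-exon model with TSS and promoter window."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]  # disjoint, sorted
    span: GenomicInterval
    tss: int
    promoter: GenomicInterval

    @property
    def exonic_length(self) -> int:
        return sum(e.width for e in self.exons)


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def parse_gtf(path: str | Path) -> list[TranscriptRecord]:
    """Parse exon features from a GTF file into transcript records.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Non-exon features are ignored. Raises ``ValueError`` naming the offending
    line number on malformed input.
    """
    exons_by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"malformed GTF line {lineno}: unknown strand {strand!r}")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinate") from exc
            if start1 < 1 or end1 < start1:
                raise ValueError(f"malformed GTF line {lineno}: bad coordinates {start1}-{end1}")
            attrs = _parse_attributes(attrs_s)
            if "gene_id" not in attrs:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id attribute")
            gene_id = attrs["gene_id"]
            tx_id = attrs.get("transcript_id", gene_id)
            biotype = attrs.get("transcript_biotype", attrs.get("gene_biotype", ""))
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            rec = exons_by_tx.setdefault(
                tx_id,
                {"gene_id": gene_id, "biotype": biotype, "chrom": chrom,
                 "strand": strand, "exons": []},
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(
                    f"malformed GTF line {lineno}: transcript {tx_id} spans "
                    f"multiple chromosomes or strands"
                )
            rec["exons"].append(iv)
    return [
        TranscriptRecord(
            gene_id=rec["gene_id"],
            transcript_id=tx_id,
            biotype=rec["biotype"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"], key=lambda e: e.start)),
        )
        for tx_id, rec in exons_by_tx.items()
    ]


def promoter_window(
    tss: int,
    strand: str,
    *,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom: str = ".",
    chrom_length: int | None = None,
    strand_aware: bool = True,
) -> GenomicInterval:
    """Promoter window around a TSS, strand-oriented by default and clipped at 0.

    On the + strand (or with ``strand_aware=False``) the window is
    ``[tss - upstream, tss + downstream)``; on the - strand it is mirrored to
    ``[tss - downstream, tss + upstream)``.
    """
    if strand == "-" and strand_aware:
        start, end = tss - downstream, tss + upstream
    else:
        start, end = tss - upstream, tss + downstream
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, end, strand)


def build_unique_gene_models(
    transcripts: list[TranscriptRecord],
    coding_only: bool = True,
    *,
    strand_aware_promoters: bool = True,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, UniqueGeneModel]:
    """Build one merged-exon gene model per gene.

    With ``coding_only`` (default) only transcripts with a protein_coding
    biotype contribute. A gene whose transcripts disagree on chromosome or
    strand raises ``ValueError`` listing the gene_id.
    """
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for tx in transcripts:
        if coding_only and tx.biotype != "protein_coding":
            continue
        by_gene.setdefault(tx.gene_id, []).append(tx)

    models: dict[str, UniqueGeneModel] = {}
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chroms = {t.chrom for t in txs}
        strands = {t.strand for t in txs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {gene_id} has transcripts on multiple chromosomes/strands: "
                f"{sorted(chroms)} {sorted(strands)}"
            )
        chrom, strand = txs[0].chrom, txs[0].strand
        exons = merge_overlapping([e for t in txs for e in t.exons])
        span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        tss = span.start if strand == "+" else span.end
        promoter = promoter_window(
            tss,
            strand,
            chrom=chrom,
            chrom_length=(chrom_lengths or {}).get(chrom),
            strand_aware=strand_aware_promoters,
        )
        models[gene_id] = UniqueGeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
            span=span,
            tss=tss,
            promoter=promoter,
        )
    return models


def write_gene_model_table(models: dict[str, UniqueGeneModel], path: str | Path) -> None:
    """Write a BED12-like TSV of gene models (one row per gene)."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstart\tend\tstrand\ttss\tn_exons\texon_starts\t"
            "exon_ends\texonic_length\tpromoter_start\tpromoter_end\n"
        )
        for gid in sorted(models):
            m = models[gid]
            fh.write(
                f"{gid}\t{m.chrom}\t{m.span.start}\t{m.span.end}\t{m.strand}\t{m.tss}\t"
                f"{len(m.exons)}\t{','.join(str(e.start) for e in m.exons)}\t"
                f"{','.join(str(e.end) for e in m.exons)}\t{m.exonic_length}\t"
                f"{m.promoter.start}\t{m.promoter.end}\n"
            )


def write_promoter_bed(models: dict[str, UniqueGeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(models):
            m = models[gid]
            fh.write(
                f"{m.chrom}\t{m.promoter.start}\t{m.promoter.end}\t{gid}\t0\t{m.strand}\n"
            )
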