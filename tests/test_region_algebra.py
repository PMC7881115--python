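import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from charflow.intervals import GenomicInterval
from charflow.region_algebra import (
    ChAR,
    annotate_regions,
    assign_nearest_gene,
    flag_tcf1_bound,
    overlap_refset,
    pool_and_merge,
    shift_tn5,
    TaggedRead,
)

from conftest import make_transcript
from charflow.genome_annotation import build_unique_gene_models


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def read(start, end, strand):
    return TaggedRead(iv(start, end, strand=strand))


class TestShiftTn5:
    def test_plus_strand_shifts_forward_4(self):
        out = shift_tn5([read(100, 136, "+")])
        assert (out[0].interval.start, out[0].interval.end) == (104, 140)

    def test_minus_strand_shifts_back_5(self):
        out = shift_tn5([read(200, 236, "-")])
        assert (out[0].interval.start, out[0].interval.end) == (195, 231)

    def test_empty_input(self):
        assert shift_tn5([]) == []

    def test_clip_at_zero_preserves_width(self, caplog):
        out = shift_tn5([read(2, 40, "-")])
        assert out[0].interval.start == 0
        assert out[0].interval.width == 38

    def test_unstranded_read_rejected(self):
        with pytest.raises(ValueError):
            shift_tn5([read(10, 40, ".")])


def brute_force_merge(intervals, mode="intersection"):
    """Independent re-coding of the stated rule: sweep the coordinate-sorted
    pool against the running region, replacing qualifying pairs (overlap >=
    half the larger width) by their overlap, iterating until stable."""
    regions = sorted({(i.chrom, i.start, i.end) for i in intervals})
    while True:
        out = []
        changed = False
        i = 0
        while i < len(regions):
            chrom, s, e = regions[i]
            j = i + 1
            while j < len(regions):
                c2, s2, e2 = regions[j]
                ov = min(e, e2) - max(s, s2) if c2 == chrom else 0
                if ov > 0 and ov >= 0.5 * max(e - s, e2 - s2):
                    if mode == "intersection":
                        s, e = max(s, s2), min(e, e2)
                    else:
                        s, e = min(s, s2), max(e, e2)
                    changed = True
                    j += 1
                else:
                    break
            out.append((chrom, s, e))
            i = j
        regions = sorted(set(out))
        if not changed:
            return regions


class TestPoolAndMerge:
    def test_below_half_overlap_keeps_both(self):
        chars = pool_and_merge([[iv(100, 200)], [iv(150, 260)]])
        assert [(c.interval.start, c.interval.end) for c in chars] == [
            (100, 200), (150, 260)
        ]

    def test_qualifying_pair_replaced_by_intersection(self):
        chars = pool_and_merge([[iv(100, 200)], [iv(120, 210)]])
        assert [(c.interval.start, c.interval.end) for c in chars] == [(120, 200)]

    def test_identical_peaks_collapse(self):
        chars = pool_and_merge([[iv(100, 200)], [iv(100, 200)]])
        assert len(chars) == 1
        assert chars[0].id == "chr1:100-200"

    def test_union_mode(self):
        chars = pool_and_merge([[iv(100, 200)], [iv(120, 210)]], merge_mode="union")
        assert [(c.interval.start, c.interval.end) for c in chars] == [(100, 210)]

    def test_mixed_chromosome_naming_rejected(self):
        with pytest.raises(ValueError, match="chr1"):
            pool_and_merge([[iv(100, 200, chrom="chr1")], [iv(100, 200, chrom="1")]])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.integers(0, 2000), st.integers(50, 400)),
            min_size=1, max_size=20,
        )
    )
    def test_matches_independent_brute_force(self, raw):
        peaks = [iv(s, s + w) for s, w in raw]
        got = [(c.interval.chrom, c.interval.start, c.interval.end)
               for c in pool_and_merge([peaks])]
        assert got == brute_force_merge(peaks)

    def test_outputs_contained_in_some_input(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 5000, size=30)
        widths = rng.integers(100, 600, size=30)
        peaks = [iv(int(s), int(s + w)) for s, w in zip(starts, widths)]
        chars = pool_and_merge([peaks])
        assert len(chars) <= len(peaks)
        for c in chars:
            assert any(
                p.start <= c.interval.start and c.interval.end <= p.end for p in peaks
            )


class TestAnnotateRegions:
    def test_promoter_beats_exon(self, toy_gene_models):
        # geneA promoter is [8000, 11000); place a ChAR overlapping both the
        # promoter and geneA's first exon
        chars = [ChAR(interval=iv(9_900, 10_100), id="x")]
        assert annotate_regions(chars, toy_gene_models)[0].annotation == "promoter"

    def test_intronic_region(self, toy_gene_models):
        chars = [ChAR(interval=iv(11_200, 11_400), id="x")]  # between geneA exons
        assert annotate_regions(chars, toy_gene_models)[0].annotation == "intron"

    def test_intergenic_fallback(self, toy_gene_models):
        chars = [ChAR(interval=iv(100_000, 100_200), id="x")]
        assert annotate_regions(chars, toy_gene_models)[0].annotation == "intergenic"

    def test_labels_form_partition_and_match_brute_force(self, toy_gene_models):
        rng = np.random.default_rng(0)
        chars = [
            ChAR(interval=iv(int(s), int(s) + 200), id=f"c{i}")
            for i, s in enumerate(rng.integers(0, 210_000, size=300))
        ]
        annotated = annotate_regions(chars, toy_gene_models)
        assert all(c.annotation is not None for c in annotated)
        for c in annotated:
            expected = "intergenic"
            models = toy_gene_models.values()
            if any(c.interval.overlaps(m.promoter) for m in models):
                expected = "promoter"
            elif any(c.interval.overlaps(e) for m in models for e in m.exons):
                expected = "exon"
            elif any(c.interval.overlaps(m.span) for m in models):
                expected = "intron"
            assert c.annotation == expected, c.id


class TestAssignNearestGene:
    def test_gap_within_limit(self):
        models = build_unique_gene_models(
            [make_transcript("g", [(40_000, 50_000)])]
        )
        chars = assign_nearest_gene(
            [ChAR(interval=iv(10_000, 10_100), id="x")], models
        )
        assert chars[0].assigned_gene == "g"
        assert chars[0].distance_to_gene == 29_900

    def test_gap_beyond_limit_unassigned(self):
        models = build_unique_gene_models(
            [make_transcript("g", [(70_000, 80_000)])]
        )
        chars = assign_nearest_gene(
            [ChAR(interval=iv(10_000, 10_100), id="x")], models
        )
        assert chars[0].assigned_gene is None

    def test_overlap_gives_distance_zero(self, toy_gene_models):
        chars = assign_nearest_gene(
            [ChAR(interval=iv(12_100, 12_300), id="x")], toy_gene_models
        )
        assert chars[0].assigned_gene == "geneA"
        assert chars[0].distance_to_gene == 0

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        txs = []
        pos = 0
        for i in range(60):
            pos += int(rng.integers(2_000, 8_000))
            txs.append(make_transcript(f"g{i:03d}", [(pos, pos + 1_500)]))
        models = build_unique_gene_models(txs)
        chars = [
            ChAR(interval=iv(int(s), int(s) + 300), id=f"c{i}")
            for i, s in enumerate(rng.integers(0, pos, size=200))
        ]
        assign_nearest_gene(chars, models, max_distance=50_000)
        for c in chars:
            best = None
            for gid, m in models.items():
                g = c.interval.gap_to(m.span)
                if g is not None and g <= 50_000 and (best is None or (g, gid) < best):
                    best = (g, gid)
            if best is None:
                assert c.assigned_gene is None
            else:
                assert (c.distance_to_gene, c.assigned_gene) == best


class TestFlagTcf1:
    @pytest.mark.parametrize(
        "site,expected",
        [
            ((35_000, 35_015), True),    # 5 kb upstream of geneB span [40000,45000)
            ((60_000, 60_015), False),   # 15 kb downstream
            ((42_000, 42_015), True),    # inside gene body
        ],
    )
    def test_window_rule(self, toy_gene_models, site, expected):
        flags = flag_tcf1_bound(toy_gene_models, [iv(*site)], window=10_000)
        assert flags["geneB"] is expected


class TestOverlapRefset:
    def test_single_bp_overlap_counts(self):
        chars = [ChAR(interval=iv(100, 200), id="c")]
        assert "c" in overlap_refset(chars, [iv(199, 300)])

    def test_half_open_boundary_excluded(self):
        chars = [ChAR(interval=iv(100, 200), id="c")]
        assert overlap_refset(chars, [iv(200, 300)]) == {}

    def test_empty_refset_rejected(self):
        with pytest.raises(ValueError):
            overlap_refset([ChAR(interval=iv(0, 10), id="c")], [])

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(5)
        chars = [
            ChAR(interval=iv(int(s), int(s) + int(w)), id=f"c{i}")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 3_000, 25), rng.integers(50, 500, 25))
            )
        ]
        refs = [
            iv(int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 3_000, 15), rng.integers(50, 500, 15))
        ]
        got = overlap_refset(chars, refs)
        for c in chars:
            expected = sorted(
                (r for r in refs if c.interval.overlaps(r)),
                key=lambda r: (r.chrom, r.start, r.end),
            )
            assert got.get(c.id, []) == expected
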