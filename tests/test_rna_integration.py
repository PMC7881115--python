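import numpy as np
import pandas as pd
import pytest

from charflow.genome_annotation import build_unique_gene_models
from charflow.intervals import GenomicInterval
from charflow.region_algebra import ChAR
from charflow.rna_integration import (
    build_signatures,
    call_degs,
    char_gene_pairs,
    gsea_preranked,
    module_expression_summary,
)

from conftest import make_transcript


def de_table(rows):
    return pd.DataFrame(rows, columns=["feature_id", "log2FC", "q_value"])


class TestCallDegs:
    def setup_method(self):
        self.rpkm = pd.DataFrame(
            {"s1": [3.0, 5.0, 0.4], "s2": [2.0, 4.0, 0.5]},
            index=["g_up", "g_weak", "g_low"],
        )

    def test_threshold_and_filter_rules(self):
        de = de_table([
            ("g_up", np.log2(1.6), 0.01),    # passes
            ("g_weak", np.log2(1.4), 0.001),  # FC below 1.5
            ("g_low", 2.0, 0.01),             # fails 1-RPKM filter
        ])
        up, down = call_degs(de, self.rpkm)
        assert up == ["g_up"] and down == []

    def test_downregulated_side(self):
        de = de_table([("g_up", -1.0, 0.01)])
        up, down = call_degs(de, self.rpkm)
        assert down == ["g_up"] and up == []


class TestBuildSignatures:
    def test_top_n_up_takes_most_upregulated_significant(self):
        rows = [(f"g{i}", i / 10.0, 0.01) for i in range(1, 201)]
        sig = build_signatures(de_table(rows), "top_n_up", n=150)
        assert len(sig) == 150
        assert sig[0] == "g200"  # highest log2FC first

    def test_thresholded_up_rule(self):
        rows = [("a", 1.5, 0.01), ("b", 0.5, 0.01), ("c", 2.0, 0.2),
                ("d", 1.0, 0.04), ("e", -2.0, 0.01)]
        sig = build_signatures(de_table(rows), "thresholded_up",
                               lfc_threshold=1.0, q_threshold=0.05)
        assert sorted(sig) == ["a", "d"]

    def test_fewer_qualifying_than_n_returns_all(self):
        rows = [("a", 2.0, 0.01), ("b", 1.0, 0.01)]
        assert len(build_signatures(de_table(rows), "top_n_up", n=150)) == 2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_signatures(de_table([]), "top_n_up")


def es_oracle(ranked, members, p):
    """Brute-force running sum over the descending-sorted list."""
    order = sorted(ranked, key=lambda g: (-ranked[g], g))
    w = {g: abs(ranked[g]) ** p for g in order}
    hit_sum = sum(w[g] for g in order if g in members)
    n_miss = sum(1 for g in order if g not in members)
    running, best = 0.0, 0.0
    for g in order:
        running += w[g] / hit_sum if g in members else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaPreranked:
    def test_top_gene_set_reaches_plus_one(self):
        ranked = {"g1": 2.0, "g2": 1.0, "g3": 1.0}
        res = gsea_preranked(ranked, ["g1"], n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_bottom_gene_set_reaches_minus_one(self):
        ranked = {"g1": 2.0, "g2": 1.0, "g3": 1.0}
        res = gsea_preranked(ranked, ["g3"], n_perm=50, seed=0)
        assert res.es == pytest.approx(-1.0)

    def test_full_list_set_is_an_error(self):
        with pytest.raises(ValueError):
            gsea_preranked({"a": 1.0, "b": 0.5}, ["a", "b"], n_perm=10)

    def test_disjoint_set_is_an_error(self):
        with pytest.raises(ValueError):
            gsea_preranked({"a": 1.0, "b": 0.5}, ["zzz"], n_perm=10)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_matches_brute_force_on_random_small_lists(self, weight_p):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(5, 21))
            genes = [f"g{i}" for i in range(n)]
            ranked = {g: float(rng.normal()) for g in genes}
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            res = gsea_preranked(ranked, sorted(members), weight_p=weight_p,
                                 n_perm=10, seed=1)
            assert res.es == pytest.approx(
                es_oracle(ranked, members, weight_p)
            )

    def test_top_decile_set_is_significant(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=300))[::-1]
        ranked = {f"g{i}": float(s) for i, s in enumerate(scores)}
        top = [f"g{i}" for i in range(25)]  # drawn from the top decile
        res = gsea_preranked(ranked, top, n_perm=1000, seed=5)
        assert res.p_value < 0.05
        assert res.nes > 0 and np.sign(res.nes) == np.sign(res.es)

    def test_p_bounded_below_by_permutation_count(self):
        rng = np.random.default_rng(8)
        ranked = {f"g{i}": float(s) for i, s in enumerate(rng.normal(size=100))}
        res = gsea_preranked(ranked, [max(ranked, key=ranked.get)], n_perm=200, seed=2)
        assert res.p_value >= 1 / (200 + 1)


@pytest.fixture
def pairing_setup():
    txs = [
        make_transcript("gene_up", [(100_000, 105_000)]),
        make_transcript("gene_far", [(500_000, 505_000)]),
    ]
    models = build_unique_gene_models(txs)
    chars = [
        ChAR(interval=GenomicInterval("chr1", 88_000, 88_400), id="near"),   # 11.6 kb
        ChAR(interval=GenomicInterval("chr1", 460_000, 460_400), id="far"),  # 39.6 kb
        ChAR(interval=GenomicInterval("chr1", 101_000, 101_400), id="inside"),
    ]
    char_diff = pd.DataFrame(
        {
            "feature_id": ["near", "far", "inside"],
            "log2FC": [2.0, -1.5, 1.2],
            "p_value": [0.01, 0.02, 0.03],
        }
    )
    return models, chars, char_diff


class TestCharGenePairs:
    def test_pairs_within_limit_and_overlap(self, pairing_setup):
        models, chars, char_diff = pairing_setup
        up = de_table([("gene_up", 3.0, 0.01)])
        out = char_gene_pairs(up, de_table([]), chars, char_diff, models)
        assert set(out.char_id) == {"near", "inside"}
        inside = out[out.char_id == "inside"].iloc[0]
        assert inside.distance == 0
        near = out[out.char_id == "near"].iloc[0]
        assert near.distance == 100_000 - 88_400

    def test_gene_with_no_close_differential_char_dropped(self, pairing_setup):
        models, chars, char_diff = pairing_setup
        up = de_table([("gene_far", 3.0, 0.01)])
        out = char_gene_pairs(up, de_table([]), chars, char_diff, models)
        assert out.empty

    def test_output_invariants_hold_by_construction(self, pairing_setup):
        models, chars, char_diff = pairing_setup
        up = de_table([("gene_up", 3.0, 0.01)])
        down = de_table([("gene_far", -2.0, 0.01)])
        out = char_gene_pairs(up, down, chars, char_diff, models,
                              pairing_limit=15_000)
        stats = char_diff.set_index("feature_id")
        for _, row in out.iterrows():
            assert row.distance <= 15_000
            assert stats.loc[row.char_id, "p_value"] < 0.05
            assert row.gene_rank_group in ("top50_up", "top50_down")


class TestModuleExpression:
    def test_dedupe_scaling_and_tcf1_fraction(self):
        models_chars = [
            ChAR(interval=GenomicInterval("chr1", 0, 100), id=f"c{i}")
            for i in range(5)
        ]
        genes = ["gA", "gA", "gB", "gC", "gD"]  # gA hit by two ChARs in module 1
        for ch, g in zip(models_chars, genes):
            ch.assigned_gene = g
            ch.distance_to_gene = 0
        labels = {"c0": 1, "c1": 1, "c2": 1, "c3": 1, "c4": 2}
        expr = pd.DataFrame(
            {"cond1": [10.0, 1.0, 4.0, 7.0], "cond2": [20.0, 2.0, 4.0, 7.0],
             "cond3": [30.0, 3.0, 4.0, 7.0]},
            index=["gA", "gB", "gC", "gD"],
        )
        tcf1 = {"gA": True, "gB": True, "gC": False, "gD": False}
        out = module_expression_summary(labels, models_chars, expr, tcf1)
        mod1 = out[out.module == 1]
        assert set(mod1.gene_id) == {"gA", "gB", "gC"}
        assert len(mod1) == 9  # 3 genes x 3 conditions (gA once)
        ga = mod1[mod1.gene_id == "gA"].sort_values("condition")
        assert ga.scaled_expression.tolist() == [0.0, 0.5, 1.0]
        gc = mod1[mod1.gene_id == "gC"]
        assert (gc.scaled_expression == 0.0).all()  # constant expression
        genes1 = mod1.drop_duplicates("gene_id")
        assert genes1.tcf1_bound.mean() == pytest.approx(2 / 3)

    def test_distant_genes_excluded(self):
        ch = ChAR(interval=GenomicInterval("chr1", 0, 100), id="c0")
        ch.assigned_gene, ch.distance_to_gene = "g", 80_000
        expr = pd.DataFrame({"c1": [1.0], "c2": [2.0]}, index=["g"])
        out = module_expression_summary({"c0": 1}, [ch], expr,
                                        max_gene_distance=50_000)
        assert out.empty
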