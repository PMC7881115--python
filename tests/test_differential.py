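import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from charflow.atac_quant import CountMatrix
from charflow.differential import (
    bh_adjust,
    call_differential,
    fisher_test,
    nb_exact_test,
    tmm_factors,
)


def make_matrix(counts, libs=None):
    counts = np.asarray(counts)
    return CountMatrix(
        feature_ids=[f"f{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        library_sizes=np.asarray(libs if libs is not None else counts.sum(axis=0)),
    )


def tmm_oracle(counts, libs, trim_m=0.30, trim_a=0.05):
    """Direct re-coding of the weighted trimmed-mean-of-M computation."""
    counts = np.asarray(counts, float)
    p = counts / libs
    uq = np.array(
        [np.quantile(p[:, j][counts[:, j] > 0], 0.75) for j in range(p.shape[1])]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.zeros(p.shape[1])
    for j in range(p.shape[1]):
        if j == ref:
            continue
        keep = (counts[:, j] > 0) & (counts[:, ref] > 0)
        m = np.log2(p[keep, j] / p[keep, ref])
        a = 0.5 * np.log2(p[keep, j] * p[keep, ref])
        w = (libs[j] - counts[keep, j]) / (libs[j] * counts[keep, j]) + (
            libs[ref] - counts[keep, ref]
        ) / (libs[ref] * counts[keep, ref])
        n = len(m)
        rm = stats.rankdata(m, method="ordinal")
        ra = stats.rankdata(a, method="ordinal")
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        k2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if k2.sum() and not np.isclose(np.abs(m[k2]).max(), 0, atol=1e-10):
            logf[j] = np.sum(m[k2] / w[k2]) / np.sum(1 / w[k2])
    f = 2.0**logf
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        m = make_matrix(np.tile([[10], [50], [200]], (1, 3)))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_doubled_column_absorbed_by_library_size(self):
        a = np.array([10, 50, 200, 35, 90])
        m = make_matrix(np.column_stack([a, 2 * a]))
        assert np.allclose(tmm_factors(m), 1.0)

    def test_matches_independent_direct_computation(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(5, 0.05, size=(50, 4)) + 1
        libs = counts.sum(axis=0).astype(float)
        got = tmm_factors(make_matrix(counts))
        assert np.allclose(got, tmm_oracle(counts, libs))

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(80, 5)) + 1
        f = tmm_factors(make_matrix(counts))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(make_matrix([[1, 0], [2, 0]], libs=[3, 1]))


class TestNBExactTest:
    def test_balanced_split_dispersion_zero_gives_p_one(self):
        m = make_matrix([[5, 5]], libs=[100, 100])
        res = nb_exact_test(m, ["A", "B"], dispersion=0.0, norm_factors=np.ones(2))
        assert res.p_value[0] == pytest.approx(1.0)

    def test_extreme_split_small_p_and_large_lfc(self):
        # one group all zero, the other large: p near the enumeration minimum
        counts = np.array([[100, 100, 0, 0]])
        m = make_matrix(counts, libs=[1000] * 4)
        res = nb_exact_test(
            m, ["A", "A", "B", "B"], dispersion=0.0, norm_factors=np.ones(4)
        )
        # under the binomial split null, the minimum is 2 * 0.5^200
        assert res.p_value[0] < 1e-50
        assert res.log2FC[0] < -5  # B over A: strongly negative

    def test_all_zero_feature_flagged_with_p_one(self):
        m = make_matrix([[0, 0, 0, 0], [10, 12, 9, 11]], libs=[100] * 4)
        res = nb_exact_test(m, ["A", "A", "B", "B"], dispersion=0.1,
                            norm_factors=np.ones(4))
        assert res.all_zero[0]
        assert res.p_value[0] == 1.0 and res.log2FC[0] == 0.0

    def test_direction_follows_groups_argument(self):
        counts = np.array([[10, 12, 100, 120]])
        m = make_matrix(counts, libs=[1000] * 4)
        res_ab = nb_exact_test(m, ["A", "A", "B", "B"], dispersion=0.0,
                               norm_factors=np.ones(4), groups=("A", "B"))
        res_ba = nb_exact_test(m, ["A", "A", "B", "B"], dispersion=0.0,
                               norm_factors=np.ones(4), groups=("B", "A"))
        assert res_ab.log2FC[0] == pytest.approx(-res_ba.log2FC[0])
        assert res_ab.log2FC[0] > 2.5

    def test_null_type_one_error_calibrated(self):
        # small, fast null check; the full grid runs in the acceptance suite
        rng = np.random.default_rng(11)
        n_feat, disp = 1500, 0.1
        means = rng.uniform(30, 200, n_feat)
        r = 1 / disp
        counts = rng.negative_binomial(r, r / (r + means[:, None]), size=(n_feat, 4))
        res = nb_exact_test(make_matrix(counts), ["A", "A", "B", "B"])
        frac = (res.p_value < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / n_feat)
        assert abs(frac - 0.05) < 2 * sd

    def test_three_groups_rejected(self):
        m = make_matrix([[1, 2, 3]], libs=[10, 10, 10])
        with pytest.raises(ValueError):
            nb_exact_test(m, ["A", "B", "C"])


class TestFisherMode:
    def test_agrees_in_direction_with_nb_test(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(40, 4))
        counts[:10, 2:] *= 4
        m = make_matrix(counts)
        nb = nb_exact_test(m, ["A", "A", "B", "B"])
        fi = fisher_test(m, ["A", "A", "B", "B"])
        assert np.all(np.sign(nb.log2FC[:10]) == np.sign(fi.log2FC[:10]))
        assert (fi.p_value[:10] < 0.05).all()


def bh_oracle(p):
    """Textbook step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [1.5], [-0.1]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=500))
    def test_matches_brute_force_step_up(self, p):
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-6, 1, 1000)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDifferential:
    @pytest.mark.parametrize(
        "lfc,q,expected",
        [(1.2, 0.01, "up"), (0.9, 0.001, "unchanged"), (-3.0, 0.2, "unchanged"),
         (-1.5, 0.01, "down")],
    )
    def test_threshold_rules(self, lfc, q, expected):
        df = pd.DataFrame({"feature_id": ["f"], "log2FC": [lfc], "q_value": [q]})
        out = call_differential(df, lfc_threshold=1.0, q_threshold=0.05)
        assert out.call[0] == expected

    def test_nonpositive_threshold_rejected(self):
        df = pd.DataFrame({"feature_id": ["f"], "log2FC": [1.0], "q_value": [0.01]})
        with pytest.raises(ValueError):
            call_differential(df, lfc_threshold=0.0)
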