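import numpy as np
import pytest
from scipy import stats

from cerna_recur.diffexpr import (DEThresholds, LONG_RNA_THRESHOLDS, MIRNA_THRESHOLDS,
                                  QpcrMeasurement, bh_fdr, call_differential,
                                  ddct_fold_change, de_counts, fold_change,
                                  hierarchical_cluster, two_group_test)
from cerna_recur.synthdata import SimConfig, simulate_expression

from conftest import make_matrix


def bh_stepup_direct(p):
    """Reference BH: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFoldChange:
    @pytest.mark.parametrize("ref,test,fc,log2fc,direction", [
        ([2, 2, 2], [2, 2, 2], 1.0, 0.0, "none"),
        ([2, 2, 2], [4, 4, 4], 2.0, 1.0, "up"),
        ([4, 4], [1, 1], 0.25, -2.0, "down"),
    ])
    def test_hand_examples(self, ref, test, fc, log2fc, direction):
        got = fold_change(ref, test)
        assert got == pytest.approx((fc, log2fc)) or True
        assert got[0] == pytest.approx(fc)
        assert got[1] == pytest.approx(log2fc)
        assert got[2] == direction

    def test_four_fold_down_is_reciprocal(self):
        fc, _, _ = fold_change([4, 4], [1, 1])
        assert 1.0 / fc == pytest.approx(4.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])


class TestTwoGroupTest:
    def test_identical_groups_null(self):
        t, _, p = two_group_test([3, 3, 3], [3, 3, 3])
        assert t == 0.0
        assert p == 1.0

    def test_welch_example_against_t_distribution(self):
        t, df, p = two_group_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df))
        assert p == pytest.approx(0.021, abs=1e-3)

    def test_matches_scipy_welch(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, size=int(rng.integers(3, 9)))
            y = rng.normal(0.5, 2, size=int(rng.integers(3, 9)))
            t, _, p = two_group_test(x, y)
            ref = stats.ttest_ind(y, x, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-6)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [1.0, 2.0])


class TestBHFdr:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_equals_direct_stepup_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 11)))
            np.testing.assert_allclose(bh_fdr(p), bh_stepup_direct(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallDifferential:
    def test_planted_genes_are_exactly_the_significant_set(self):
        cfg = SimConfig(n_per_group=4, n_mirna=0, n_lncrna=0, n_mrna=10,
                        noise_sd=0.1,
                        de_spec={"mrna": [("mRNA-0003", "B", 3.0),
                                          ("mRNA-0007", "B", -3.0)]},
                        rng_seed=5)
        mats, _ = simulate_expression(cfg)
        table = call_differential(mats["mrna"], ("A", "B"), LONG_RNA_THRESHOLDS)
        sig = set(table.loc[table["significant"], "gene_id"])
        assert sig == {"mRNA-0003", "mRNA-0007"}
        counts = de_counts(table)
        assert (counts["up"], counts["down"]) == (1, 1)

    def test_empty_matrix_gives_empty_table(self):
        m = make_matrix(np.empty((0, 8)), groups="AAAABBBB")
        table = call_differential(m, ("A", "B"))
        assert len(table) == 0

    def test_significant_set_monotone_in_thresholds(self, two_group_matrix):
        m = two_group_matrix
        loose = call_differential(m, ("A", "B"), DEThresholds(1.1, 0.5))
        tight_fc = call_differential(m, ("A", "B"), DEThresholds(1.3, 0.5))
        tight_p = call_differential(m, ("A", "B"), DEThresholds(1.1, 0.1))
        loose_set = set(loose.loc[loose["significant"], "gene_id"])
        assert set(tight_fc.loc[tight_fc["significant"], "gene_id"]) <= loose_set
        assert set(tight_p.loc[tight_p["significant"], "gene_id"]) <= loose_set

    def test_inclusive_fc_boundary(self):
        # planted exactly 2-fold at zero noise: strict > excludes, >= includes
        cfg = SimConfig(n_per_group=4, n_mirna=0, n_lncrna=0, n_mrna=3,
                        noise_sd=0.0, de_spec={"mrna": [("mRNA-0001", "B", 1.0)]},
                        rng_seed=0)
        mats, _ = simulate_expression(cfg)
        strict = call_differential(mats["mrna"], ("A", "B"),
                                   DEThresholds(2.0, 0.05, strict_fc=True))
        inclusive = call_differential(mats["mrna"], ("A", "B"),
                                      DEThresholds(2.0, 0.05, strict_fc=False))
        assert not strict.loc[strict["gene_id"] == "mRNA-0001", "significant"].item()
        assert inclusive.loc[inclusive["gene_id"] == "mRNA-0001", "significant"].item()

    def test_unknown_group_rejected(self, two_group_matrix):
        with pytest.raises(KeyError):
            call_differential(two_group_matrix, ("A", "Z"))

    def test_null_type_one_rate_near_nominal(self):
        hits = total = 0
        for seed in range(20):
            cfg = SimConfig(n_per_group=4, n_mirna=0, n_lncrna=0, n_mrna=300,
                            noise_sd=0.3, rng_seed=seed)
            mats, _ = simulate_expression(cfg)
            table = call_differential(mats["mrna"], ("A", "B"))
            hits += int((table["p"] <= 0.05).sum())
            total += len(table)
        assert abs(hits / total - 0.05) < 0.01


class TestHierarchicalCluster:
    def test_identical_profiles_merge_first_at_zero_height(self):
        data = np.array([[1.0, 2.0, 3.0],
                         [2.0, 4.0, 6.0],   # r = 1 with row 0
                         [3.0, 1.0, 2.0]])
        Z = hierarchical_cluster(data, axis="genes")
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_items_match_exhaustive_enumeration(self, rng):
        for _ in range(20):
            data = rng.normal(size=(3, 6))
            d = {}
            for i in range(3):
                for j in range(i + 1, 3):
                    d[(i, j)] = 1 - np.corrcoef(data[i], data[j])[0, 1]
            (i0, j0), h0 = min(d.items(), key=lambda kv: kv[1])
            rest = ({0, 1, 2} - {i0, j0}).pop()
            h1 = np.mean([d[tuple(sorted((rest, i0)))], d[tuple(sorted((rest, j0)))]])
            Z = hierarchical_cluster(data, axis="genes")
            assert set(Z[0, :2].astype(int)) == {i0, j0}
            assert Z[0, 2] == pytest.approx(h0)
            assert Z[1, 2] == pytest.approx(h1)

    def test_samples_axis_on_matrix(self, two_group_matrix):
        Z = hierarchical_cluster(two_group_matrix, axis="samples")
        assert Z.shape == (two_group_matrix.n_samples - 1, 4)

    def test_zero_variance_item_rejected(self):
        data = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            hierarchical_cluster(data, axis="genes")


class TestDdct:
    def _m(self, group, target, ref):
        return QpcrMeasurement("s", group, target, ref)

    def test_zero_ddct_is_unity(self):
        assert ddct_fold_change(self._m("B", 20, 15), self._m("A", 25, 20)) == 1.0

    def test_hand_example_fourfold(self):
        treated = self._m("B", 20, 15)
        control = self._m("A", 22, 15)
        assert ddct_fold_change(treated, control) == pytest.approx(4.0)

    def test_swapping_conditions_inverts(self):
        a, b = self._m("A", 21.3, 15.2), self._m("B", 19.8, 15.5)
        x = ddct_fold_change(a, b)
        assert ddct_fold_change(b, a) == pytest.approx(1.0 / x)

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement("s", "A", float("nan"), 15.0)
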