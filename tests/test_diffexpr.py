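"""ANOVA / t-test / BH / SNK statistics and the DE filter cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from antarray import diffexpr, simdata
from antarray.diffexpr import Thresholds
from conftest import run_to_contigs


class TestOneWayAnova:
    def test_all_values_identical_degenerate(self):
        assert diffexpr.one_way_anova([[5, 5], [5, 5], [5, 5]]) == (0.0, 1.0)

    def test_identical_group_profiles(self):
        f, p = diffexpr.one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_within_variance_separates_perfectly(self):
        f, p = diffexpr.one_way_anova([[0, 0], [1, 1], [2, 2]])
        assert np.isinf(f) and p < 1e-6
        # the exhaustive permutation oracle attains its floor here:
        # only relabelings keeping each group constant reach F = inf
        assert oracles.anova_permutation_p([[0, 0], [1, 1], [2, 2]]) == \
            pytest.approx(6 / 90)

    def test_agrees_with_permutation_oracle_on_noisy_data(self):
        groups = [[1.0, 2.0, 1.5], [2.5, 3.5, 3.0], [1.2, 2.2, 1.9]]
        _, p = diffexpr.one_way_anova(groups)
        p_perm = oracles.anova_permutation_p(groups)
        assert abs(p - p_perm) < 0.1
        assert (p <= 0.05) == (p_perm <= 0.05)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.one_way_anova([[1], [2, 3]])


class TestTwoGroupTTest:
    def test_identical_groups(self):
        assert diffexpr.two_group_ttest([5, 5], [5, 5]) == (0.0, 1.0)

    def test_swap_flips_sign_only(self):
        t1, p1 = diffexpr.two_group_ttest([1, 2, 3], [4, 5, 7])
        t2, p2 = diffexpr.two_group_ttest([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_against_exhaustive_permutation_oracle(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        _, p = diffexpr.two_group_ttest(a, b)
        p_perm = oracles.ttest_permutation_p(a, b)
        # 70 relabelings: the permutation distribution is coarse, so the
        # two p-values agree only loosely in value but in decision
        assert abs(p - p_perm) < 0.15
        assert (p <= 0.05) == (p_perm <= 0.05)

    def test_zero_variance_unequal_means_degenerate(self):
        t, p = diffexpr.two_group_ttest([1, 1], [2, 2])
        assert np.isinf(t) and p == 0.0


class TestBHAdjust:
    def test_constant_vector_unchanged(self):
        np.testing.assert_array_equal(diffexpr.bh_adjust([0.3, 0.3, 0.3]),
                                      [0.3, 0.3, 0.3])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_identity(self):
        np.testing.assert_array_equal(diffexpr.bh_adjust([0.73]), [0.73])

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_array_equal(diffexpr.bh_adjust(p),
                                          oracles.bh_step_up(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(30)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(diffexpr.bh_adjust(p), sm, rtol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.5, 1.2])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.random(200)
        adj = diffexpr.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestSNK:
    def test_equal_means_single_subset(self):
        subsets = diffexpr.snk_posthoc([3.0, 3.0, 3.0], [4, 4, 4],
                                       mse=1.0, df_error=9)
        assert subsets == [(0, 1, 2)]

    def test_vanishing_mse_separates_all(self):
        subsets = diffexpr.snk_posthoc([1.0, 2.0, 3.0], [4, 4, 4],
                                       mse=1e-12, df_error=9)
        assert subsets == [(0,), (1,), (2,)]

    def test_close_pair_separated_from_distant_group(self):
        # means (10, 10.1, 20), n=4 each, MSE=0.04, df=9:
        # q(.05, 2, 9) * sqrt(.04/4) ~= 0.32 > 0.1 -> {1,2} homogeneous;
        # 20 is ~100 range units away -> separated
        subsets = diffexpr.snk_posthoc([10.0, 10.1, 20.0], [4, 4, 4],
                                       mse=0.04, df_error=9)
        assert subsets == [(0, 1), (2,)]
        # decision verified against the numerically integrated
        # studentized-range CDF at the same stretch parameters
        q_obs = 0.1 / np.sqrt(0.04 / 4)
        assert 1 - oracles.studentized_range_cdf(q_obs, 2, 9) > 0.05
        q_far = 9.9 / np.sqrt(0.04 / 4)
        assert 1 - oracles.studentized_range_cdf(q_far, 2, 9) < 0.05

    def test_k2_equivalent_to_pooled_ttest(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n1, n2 = rng.integers(2, 10, 2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.normal(0, 1), 1, n2)
            mse = (((a - a.mean()) ** 2).sum()
                   + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
            if mse == 0:
                continue
            subsets = diffexpr.snk_posthoc([a.mean(), b.mean()], [n1, n2],
                                           mse, n1 + n2 - 2, alpha=0.05)
            snk_separates = subsets == [(0,), (1,)] or subsets == [(1,), (0,)]
            _, p = diffexpr.two_group_ttest(a, b)
            assert snk_separates == (p <= 0.05)

    def test_nonpositive_mse_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.snk_posthoc([1.0, 2.0], [4, 4], mse=0.0, df_error=6)


class TestDETable:
    def _table(self, group_values, thresholds=Thresholds()):
        """group_values: dict group -> per-gene list of replicate values."""
        groups = list(group_values)
        arrays, labels = [], []
        for g in groups:
            arr = np.asarray(group_values[g], dtype=float)
            arrays.append(arr)
            labels += [g] * arr.shape[1]
        values = np.hstack(arrays)
        from conftest import make_log_table
        table = make_log_table(np.log2(values + 1), labels)
        # rebuild as linear for de_table
        from antarray.arrayproc import ContigExpressionTable
        linear = ContigExpressionTable(
            pd.DataFrame(values, index=table.values.index,
                         columns=table.values.columns),
            table.samples)
        return diffexpr.de_table(linear, groups, thresholds)

    def test_filter_cascade_gates(self):
        rec = self._table({
            # gene 0: strong 3x difference, well expressed -> relevant
            # gene 1: expressed but under 2-fold -> not relevant
            # gene 2: below intensity cutoff -> excluded, no test
            "a": [[300, 310, 290, 305], [150, 152, 148, 150], [90, 91, 89, 90]],
            "b": [[100, 104, 98, 101], [90, 91, 89, 90], [50, 51, 49, 50]],
        })
        assert rec.loc[0, "expressed"] and rec.loc[0, "relevant"]
        assert rec.loc[1, "expressed"] and not rec.loc[1, "relevant"]
        assert rec.loc[1, "ratio"] < 2.0
        assert not rec.loc[2, "expressed"] and np.isnan(rec.loc[2, "p"])

    def test_ratio_is_larger_over_smaller(self):
        rec = self._table({"a": [[100, 100, 100, 100]],
                           "b": [[400, 400, 400, 400]]})
        assert rec.loc[0, "ratio"] == pytest.approx(4.0)

    def test_unknown_group_is_hard_error(self):
        cfg = simdata.caste_null_config(seed=0, n_contigs=10)
        table = run_to_contigs(cfg)
        with pytest.raises(KeyError):
            diffexpr.de_table(table, ["queens", "nope"], Thresholds())

    def test_invariant_to_row_and_group_order(self):
        cfg, _ = simdata.subcaste_spike_config(seed=3, n_contigs=20)
        table = run_to_contigs(cfg)
        rec1 = diffexpr.de_table(table, ["large", "tiny"], Thresholds())
        shuffled = table.values.sample(frac=1.0, random_state=0)
        from antarray.arrayproc import ContigExpressionTable
        table2 = ContigExpressionTable(shuffled, table.samples)
        rec2 = diffexpr.de_table(table2, ["tiny", "large"], Thresholds())
        merged = rec1.merge(rec2, on="contig_id", suffixes=("_1", "_2"))
        np.testing.assert_allclose(merged["p_1"], merged["p_2"])
        np.testing.assert_allclose(merged["ratio_1"], merged["ratio_2"])
        assert (merged["relevant_1"] == merged["relevant_2"]).all()

    def test_spiked_contig_recovered_across_seeds(self):
        """A 4-fold spike (log2FC 2.0) with n=4 and sd 0.25 passes the
        whole cascade in >= 90% of seeds."""
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            cfg, spiked = simdata.subcaste_spike_config(seed=s)
            table = run_to_contigs(cfg)
            rec = diffexpr.de_table(table, ["large", "tiny"], Thresholds())
            row = rec.set_index("contig_id").loc[spiked]
            hits += bool(row["relevant"])
        assert hits >= 0.90 * n_seeds

    def test_heatmap_masks_non_relevant_rows(self):
        rec = self._table({
            "a": [[300, 310, 290, 305], [90, 91, 89, 90]],
            "b": [[100, 104, 98, 101], [50, 51, 49, 50]],
        })
        mat = diffexpr.heatmap_matrix(rec)
        assert mat.iloc[0].notna().all()
        assert mat.iloc[1].isna().all()
        assert mat.isna().all(axis=1).sum() == (~rec["relevant"]).sum()


def test_snk_reported_only_for_significant_anova_contigs():
    cfg = simdata.caste_null_config(seed=1, n_contigs=30)
    table = run_to_contigs(cfg)
    rec = diffexpr.de_table(table, ["queens", "males", "workers"], Thresholds())
    sig = rec["p_adj"] <= 0.05
    assert (rec.loc[~sig & rec["expressed"], "snk_groups"] == "").all()
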