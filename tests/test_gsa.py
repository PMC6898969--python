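"""LS/KS/maxmean statistics, empirical nulls and the 2-of-3 consensus rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cortexdiff.data import ComparisonSpec, GeneSetCollection, ValidationError
from cortexdiff.gsa import (
    analyze_gene_sets,
    consensus_call,
    ks_statistic,
    ls_statistic,
    maxmean_scores,
    maxmean_test,
    random_set_pvalue,
)


class TestLsStatistic:
    def test_worked_example(self):
        assert ls_statistic([0.1, 0.01]) == pytest.approx(3.453878, abs=1e-6)

    def test_all_ones_give_zero(self):
        assert ls_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_singleton(self):
        assert ls_statistic([0.05]) == pytest.approx(2.995732, abs=1e-6)

    def test_zero_p_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            val = ls_statistic([0.0, 0.5])
        assert np.isfinite(val)


class TestKsStatistic:
    def test_worked_example(self):
        assert ks_statistic([0.01, 0.2, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_single_p_of_one_gives_zero(self):
        assert ks_statistic([1.0]) == 0.0

    def test_matches_exhaustive_index_evaluation(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.001, 1.0, size=7)
        expected = max((i + 1) / 7 - q for i, q in enumerate(sorted(p)))
        assert ks_statistic(p) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=12))
    def test_member_order_invariance(self, p):
        rng = np.random.default_rng(0)
        shuffled = list(np.array(p)[rng.permutation(len(p))])
        assert ks_statistic(p) == pytest.approx(ks_statistic(shuffled))
        assert ls_statistic(p) == pytest.approx(ls_statistic(shuffled))


class TestRandomSetPvalue:
    def test_top_k_genes_attain_minimum_p(self):
        rng = np.random.default_rng(0)
        all_p = rng.uniform(0.0005, 1.0, size=400)
        member_p = np.sort(all_p)[:10]
        _, p = random_set_pvalue(ls_statistic, member_p, all_p,
                                 n_null=1000, seed=1)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_add_one_rule_at_n_null_100(self):
        all_p = np.full(200, 0.9)
        member_p = np.full(5, 0.001)  # beats every possible null set
        _, p = random_set_pvalue(ls_statistic, member_p, all_p,
                                 n_null=100, seed=2)
        assert p == pytest.approx(1.0 / 101.0)

    def test_empirical_p_never_zero_and_monotone_in_statistic(self):
        rng = np.random.default_rng(3)
        all_p = rng.uniform(0.001, 1.0, size=300)
        seen = []
        for q in (0.5, 0.1, 0.02, 0.002):
            _, p = random_set_pvalue(ls_statistic, np.full(8, q), all_p,
                                     n_null=500, seed=11)
            assert p > 0
            seen.append(p)
        assert seen == sorted(seen, reverse=True)

    def test_oversized_set_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            random_set_pvalue(ls_statistic, np.full(11, 0.5), np.full(10, 0.5),
                              n_null=100)


class TestMaxmean:
    def test_worked_example_prefers_down_side(self):
        sp, sn = maxmean_scores(np.array([2.0, -1.0, -3.0]))
        assert sp == pytest.approx(2.0 / 3.0, abs=1e-6)
        assert sn == pytest.approx(4.0 / 3.0, abs=1e-6)

    def test_constant_positive_scores_give_up_direction(self):
        sp, sn = maxmean_scores(np.full(6, 1.7))
        assert sp == pytest.approx(1.7)
        assert sn == 0.0

    def test_planted_set_detected_null_matrix_not(self, planted_dataset):
        matrix, sheet, sets, _ = planted_dataset
        spec = ComparisonSpec("FPOS_GML", "CTRL")
        stat, direction, p = maxmean_test(
            matrix, sheet, spec, sets.sets["TNF_PRO_DEATH"],
            n_perm=200, seed=4)
        assert direction == "up"
        assert p < 0.05
        _, _, p_decoy = maxmean_test(
            matrix, sheet, spec, sets.sets["DECOY_001"], n_perm=200, seed=4)
        assert p_decoy > 0.05

    def test_tiny_permutation_space_rejected(self, planted_dataset):
        matrix, _, sets, _ = planted_dataset
        sheet = __import__("conftest").two_group_sheet(2, 2)
        sub = matrix.data.iloc[:50, :4]
        sub.columns = sheet.sample_ids
        from cortexdiff.data import ExpressionMatrix
        with pytest.raises(ValidationError, match="6 distinct"):
            maxmean_test(ExpressionMatrix(sub), sheet,
                         ComparisonSpec("FPOS_GML", "CTRL"),
                         list(sub.index[:5]), n_perm=50)


class TestConsensus:
    @pytest.mark.parametrize("ps,expected_n,expected_flag", [
        ((0.04, 0.2, 0.01), 2, True),
        ((0.04, 0.2, 0.6), 1, False),
        ((0.05, 0.05, 0.05), 0, False),  # strict inequality at the boundary
        ((0.01, 0.01, 0.01), 3, True),
    ])
    def test_two_of_three_rule(self, ps, expected_n, expected_flag):
        n, flag = consensus_call(*ps)
        assert (n, flag) == (expected_n, expected_flag)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            consensus_call(0.01, 1.5, 0.2)


class TestAnalyzeGeneSets:
    def test_planted_panels_reach_consensus_decoys_do_not(self,
                                                          planted_dataset):
        matrix, sheet, sets, _ = planted_dataset
        spec = ComparisonSpec("FPOS_GML", "CTRL")
        out = analyze_gene_sets(matrix, sheet, spec, sets,
                                n_null=1000, n_perm=300, seed=6)
        by_name = out.set_index("name")
        assert by_name.loc["TNF_PRO_DEATH", "consensus"]
        assert by_name.loc["TNF_PRO_DEATH", "maxmean_direction"] == "up"
        decoys = out[out["name"].str.startswith("DECOY")]
        assert decoys["consensus"].mean() <= 0.2

    def test_undersized_sets_skipped_not_failed(self, planted_dataset):
        matrix, sheet, _, _ = planted_dataset
        spec = ComparisonSpec("FPOS_GML", "CTRL")
        small = GeneSetCollection(sets={"tiny": matrix.gene_ids[:2],
                                        "ok": matrix.gene_ids[:6]})
        out = analyze_gene_sets(matrix, sheet, spec, small,
                                n_null=200, n_perm=100, seed=0)
        row = out.set_index("name").loc["tiny"]
        assert bool(row["skipped"]) and not bool(row["consensus"])
        assert not out.set_index("name").loc["ok", "skipped"]

    def test_consensus_rule_is_conservative_under_global_null(self):
        """Across 300 decoy sets on null data, the 2-of-3 conjunction fires
        no more often than any single test at alpha=0.05."""
        import pandas as pd
        from cortexdiff.simulate import SimulationConfig, generate_dataset
        empty = pd.DataFrame(columns=["gene", "condition", "log2fc"])
        cfg = SimulationConfig(n_genes=2000, effects=empty,
                               n_decoy_sets=300, seed=303)
        matrix, sheet, sets, _ = generate_dataset(cfg)
        spec = ComparisonSpec("FNEG_GML", "CTRL")
        out = analyze_gene_sets(matrix, sheet, spec, sets,
                                n_null=1000, n_perm=300, seed=13)
        decoys = out[out["name"].str.startswith("DECOY")]
        consensus_rate = decoys["consensus"].mean()
        single_rates = [(decoys[c] < 0.05).mean()
                        for c in ("ls_p", "ks_p", "maxmean_p")]
        assert consensus_rate <= min(single_rates)
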