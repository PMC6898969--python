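"""Moderated t-test: hyperparameter fitting, calling, overlaps, properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortexdiff.data import ComparisonSpec, ExpressionMatrix, ValidationError
from cortexdiff.rvm import (
    A_MAX,
    DegSet,
    RvmFit,
    call_degs,
    fit_rvm,
    overlap_accounting,
    rvm_ttest,
    signed_fold_change,
)
from cortexdiff.simulate import sample_gene_variances

from conftest import two_group_sheet


def _simulated_variances(a, b, d, n, seed):
    rng = np.random.default_rng(seed)
    sigma2 = sample_gene_variances(n, a, b, rng)
    return sigma2 * rng.chisquare(d, n) / d


def _matrix_from_values(values, sheet):
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sheet.sample_ids))


class TestFitRvm:
    def test_recovers_known_hyperparameters(self):
        s2 = _simulated_variances(3.0, 1.0, 18, 20000, seed=0)
        fit = fit_rvm(s2, 18)
        assert 2.5 <= fit.a <= 3.6
        assert 0.85 <= fit.b <= 1.18

    def test_zero_df_rejected(self):
        with pytest.raises(ValidationError):
            fit_rvm(np.ones(100) + np.arange(100) * 0.01, 0)

    def test_refit_reproduces_parameters(self):
        s2 = _simulated_variances(3.0, 1.0, 18, 2000, seed=4)
        f1, f2 = fit_rvm(s2, 18), fit_rvm(s2, 18)
        assert abs(f1.a - f2.a) < 1e-8
        assert abs(f1.b - f2.b) < 1e-8

    def test_degenerate_variances_raise_or_cap(self):
        flat = np.full(200, 0.5)
        with pytest.raises(ValidationError, match="degenerate"):
            fit_rvm(flat, 18)
        fit = fit_rvm(flat, 18, cap_degenerate=True)
        assert fit.a == A_MAX
        assert fit.tau == pytest.approx(0.5)

    def test_zero_variances_floored_at_first_percentile(self):
        s2 = _simulated_variances(3.0, 1.0, 18, 1000, seed=2)
        s2[:5] = 0.0
        fit = fit_rvm(s2, 18)
        assert fit.variance_floor == pytest.approx(
            np.percentile(s2[s2 > 0], 1.0))
        assert np.isfinite(fit.log_likelihood)


class TestModeratedTTest:
    def test_equal_group_means_give_t_zero_p_one(self):
        sheet = two_group_sheet(4, 4)
        base = np.array([1.0, 2.0, 1.5, 2.5])
        values = np.vstack([np.concatenate([base, base]) for _ in range(60)])
        values += np.random.default_rng(0).normal(0, 1e-6, values.shape)
        values[0] = np.concatenate([base, base])  # exactly equal means
        m = _matrix_from_values(values, sheet)
        out = rvm_ttest(m, sheet, ComparisonSpec("FPOS_GML", "CTRL"))
        assert out.iloc[0]["t_mod"] == 0.0
        assert out.iloc[0]["p"] == 1.0

    def test_capped_prior_limit_matches_known_variance_z_test(self):
        """With a capped shape and tau at the common variance, the moderated
        statistic equals the pooled t statistic and its p-value approaches
        the known-variance normal limit (prior df swamps the data)."""
        rng = np.random.default_rng(3)
        sheet = two_group_sheet(10, 10)
        common_var = 0.4
        values = rng.normal(8, np.sqrt(common_var), size=(100, 20))
        m = _matrix_from_values(values, sheet)
        fit = RvmFit(a=A_MAX, b=1.0 / (A_MAX * common_var), d=18,
                     log_likelihood=0.0, converged=True)
        out = rvm_ttest(m, sheet, ComparisonSpec("FPOS_GML", "CTRL"), fit=fit)
        xa, xb = values[:, :10], values[:, 10:]
        diff = xa.mean(axis=1) - xb.mean(axis=1)
        z = diff / np.sqrt(common_var * 0.2)
        np.testing.assert_allclose(out["p"], 2 * stats.norm.sf(np.abs(z)),
                                   rtol=1e-3)

    def test_null_calibration_at_one_percent(self, null_dataset):
        matrix, sheet, _, _ = null_dataset
        out = rvm_ttest(matrix, sheet, ComparisonSpec("FPOS_GML", "CTRL"))
        hits = int((out["p"] < 0.01).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], matrix.n_genes, 0.01)
        assert lo <= hits <= hi

    def test_swapping_groups_negates_effect_preserves_p(self, null_dataset):
        matrix, sheet, _, _ = null_dataset
        fwd = rvm_ttest(matrix, sheet, ComparisonSpec("FPOS_GML", "CTRL"))
        rev = rvm_ttest(matrix, sheet,
                        ComparisonSpec("CTRL", "FPOS_GML", 0.01, 1.5))
        np.testing.assert_allclose(rev["log2fc"], -fwd["log2fc"])
        np.testing.assert_allclose(rev["t_mod"], -fwd["t_mod"], rtol=1e-9)
        np.testing.assert_allclose(rev["p"], fwd["p"], rtol=1e-9)
        np.testing.assert_allclose(rev["fc"].abs(), fwd["fc"].abs())

    def test_singleton_group_rejected_by_name(self, null_dataset):
        matrix, sheet, _, _ = null_dataset
        trimmed = sheet.table[
            (sheet.table["group"] != "CTRL")
            | (sheet.table["sample_id"] == "CTRL_01")]
        from cortexdiff.data import SampleSheet
        with pytest.raises(ValidationError, match="CTRL"):
            rvm_ttest(matrix, SampleSheet(trimmed),
                      ComparisonSpec("FPOS_GML", "CTRL"))


class TestCallDegs:
    def _stats(self, p, log2fc):
        return pd.DataFrame({
            "p": p, "log2fc": log2fc, "fc": signed_fold_change(np.array(log2fc)),
        }, index=[f"g{i}" for i in range(len(p))])

    def test_fold_change_threshold_gates_significance(self):
        spec = ComparisonSpec("FPOS_GML", "CTRL", 0.01, 1.5)
        stats_df = self._stats([0.005, 0.005], [0.5, 0.7])
        degs = call_degs(stats_df, spec)
        # 2^0.5 = 1.41 < 1.5 excluded; 2^0.7 = 1.62 passes
        assert degs.up == ["g1"]
        assert degs.down == []

    def test_partition_identity(self, null_dataset, fpos_gml_spec):
        matrix, sheet, _, _ = null_dataset
        out = rvm_ttest(matrix, sheet, fpos_gml_spec)
        degs = call_degs(out, fpos_gml_spec)
        assert len(degs) == int(out["significant"].sum())
        assert not set(degs.up) & set(degs.down)

    def test_thresholds_act_monotonically(self, planted_dataset):
        matrix, sheet, _, _ = planted_dataset
        spec = ComparisonSpec("FPOS_GML", "CTRL")
        out = rvm_ttest(matrix, sheet, spec)
        sizes = {}
        for p_thr in (0.05, 0.01, 0.001):
            for fc_thr in (1.5, 2.0, 3.0):
                s = ComparisonSpec("FPOS_GML", "CTRL", p_thr, fc_thr)
                sizes[(p_thr, fc_thr)] = len(call_degs(out, s))
        for p_thr in (0.05, 0.01, 0.001):
            assert sizes[(p_thr, 1.5)] >= sizes[(p_thr, 2.0)] >= sizes[(p_thr, 3.0)]
        for fc_thr in (1.5, 2.0, 3.0):
            assert sizes[(0.05, fc_thr)] >= sizes[(0.01, fc_thr)] >= sizes[(0.001, fc_thr)]

    def test_sensitivity_exceeds_080_and_beats_stricter_fc(self):
        """Planted |log2FC|=1.5 effects: FC-1.5 calling is sensitive and
        strictly more sensitive than FC-2 calling."""
        rng = np.random.default_rng(12)
        genes = [f"G{i:05d}" for i in range(180, 380)]
        effects = pd.DataFrame({
            "gene": genes,
            "condition": "FPOS_GML",
            "log2fc": rng.choice([-1.5, 1.5], size=200),
        })
        from cortexdiff.simulate import SimulationConfig, generate_dataset
        cfg = SimulationConfig(n_genes=2000, effects=effects, seed=31)
        matrix, sheet, _, truth = generate_dataset(cfg)
        spec15 = ComparisonSpec("FPOS_GML", "CTRL", 0.01, 1.5)
        spec20 = ComparisonSpec("FPOS_GML", "CTRL", 0.01, 2.0)
        out = rvm_ttest(matrix, sheet, spec15)
        planted = truth.genes_with_effect("FPOS_GML")
        sens15 = len(call_degs(out, spec15).genes & planted) / len(planted)
        sens20 = len(call_degs(out, spec20).genes & planted) / len(planted)
        assert sens15 > 0.8
        assert sens15 > sens20


class TestOverlapAccounting:
    def test_two_set_example(self):
        ds1 = DegSet("c1", up=["A", "B"], down=["C"])
        ds2 = DegSet("c2", up=["B"], down=["C", "D"])
        table = overlap_accounting([ds1, ds2]).set_index(["c1", "c2"])["count"]
        assert table[(True, False)] == 1   # A only
        assert table[(False, True)] == 1   # D only
        assert table[(True, True)] == 2    # B, C shared

    def test_identical_sets_fill_only_full_intersection(self):
        sets = [DegSet(f"c{i}", up=["A", "B"], down=["C"]) for i in range(4)]
        table = overlap_accounting(sets)
        full = table[table[[f"c{i}" for i in range(4)]].all(axis=1)]
        assert full["count"].iloc[0] == 3
        assert table["count"].sum() == 3

    def test_matches_brute_force_membership_tally(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(120)]
        deg_sets = []
        for label in ("w", "x", "y", "z"):
            chosen = rng.choice(universe, size=40, replace=False)
            up = [g for g in chosen[:20]]
            down = [g for g in chosen[20:]]
            deg_sets.append(DegSet(label, up=up, down=down))
        table = overlap_accounting(deg_sets)
        labels = [ds.comparison for ds in deg_sets]
        # oracle: tally per-gene membership vectors directly
        from collections import Counter
        tally = Counter(
            tuple(g in ds.genes for ds in deg_sets)
            for g in set().union(*(ds.genes for ds in deg_sets))
        )
        for _, row in table.iterrows():
            pattern = tuple(bool(row[lab]) for lab in labels)
            assert row["count"] == tally.get(pattern, 0)
        assert table["count"].sum() == len(
            set().union(*(ds.genes for ds in deg_sets)))
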