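"""Differential testing, DMR calling, clustering, volcano."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import helpdmr as h
from helpdmr.dmr import _nan_sqeuclidean_condensed

from conftest import brute_force_pooled_t


def _matrix_from_groups(a: np.ndarray, b: np.ndarray) -> tuple[pd.DataFrame, pd.Series]:
    """Loci x samples frame with control block a and case block b."""
    values = np.hstack([a, b])
    cols = [f"c{i}" for i in range(a.shape[1])] + [f"k{i}" for i in range(b.shape[1])]
    df = pd.DataFrame(values, index=[f"f{i}" for i in range(len(values))], columns=cols)
    groups = pd.Series(
        ["control"] * a.shape[1] + ["case"] * b.shape[1], index=cols
    )
    return df, groups


class TestLocusDifferentialTest:
    def test_closed_form_example(self):
        df, groups = _matrix_from_groups(
            np.array([[0.0, 1.0, 2.0]]), np.array([[3.0, 4.0, 5.0]])
        )
        stats, qc = h.locus_differential_test(df, groups)
        assert qc == {"n_tested": 1, "n_skipped": 0}
        row = stats.iloc[0]
        assert row["delta"] == pytest.approx(3.0)
        assert row["t"] == pytest.approx(3.674, abs=1e-3)
        assert row["p_value"] == pytest.approx(0.0212, abs=2e-4)

    def test_equal_means_give_null_result(self):
        df, groups = _matrix_from_groups(
            np.array([[1.0, 2.0, 3.0]]), np.array([[3.0, 2.0, 1.0]])
        )
        stats, _ = h.locus_differential_test(df, groups)
        assert stats["t"].iloc[0] == 0.0
        assert stats["p_value"].iloc[0] == 1.0

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(100, 12))
        b = rng.normal(size=(100, 14)) + rng.normal(scale=0.5, size=(100, 1))
        df, groups = _matrix_from_groups(a, b)
        stats, _ = h.locus_differential_test(df, groups)
        for i in range(len(df)):
            t_exp, p_exp = brute_force_pooled_t(a[i], b[i])
            assert stats["t"].iloc[i] == pytest.approx(t_exp, rel=1e-10)
            assert stats["p_value"].iloc[i] == pytest.approx(p_exp, rel=1e-10)

    def test_welch_flag_matches_scipy(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(30, 8))
        b = rng.normal(scale=3.0, size=(30, 10))
        df, groups = _matrix_from_groups(a, b)
        stats, _ = h.locus_differential_test(df, groups, equal_var=False)
        ref = sps.ttest_ind(b, a, axis=1, equal_var=False)
        np.testing.assert_allclose(stats["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(stats["p_value"], ref.pvalue, rtol=1e-10)

    def test_sparse_loci_skipped_and_counted(self):
        a = np.array([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]])
        b = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 5.0]])
        df, groups = _matrix_from_groups(a, b)
        stats, qc = h.locus_differential_test(df, groups)
        assert qc == {"n_tested": 1, "n_skipped": 1}
        assert stats["fragment_id"].tolist() == ["f1"]

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(12)
        df, groups = _matrix_from_groups(
            rng.normal(size=(3000, 12)), rng.normal(size=(3000, 14))
        )
        stats, _ = h.locus_differential_test(df, groups)
        ks = sps.kstest(stats["p_value"], "uniform")
        assert ks.statistic < 1.63 / np.sqrt(len(stats))


class TestCallDmrs:
    def test_strict_thresholds(self):
        stats = pd.DataFrame(
            {
                "fragment_id": ["a", "b", "c", "d"],
                "delta": [0.6, 0.5, -0.7, 0.8],
                "t": [4.0, 3.0, -5.0, 2.0],
                "p_value": [0.005, 0.005, 0.001, 0.01],
            }
        )
        d = h.call_dmrs(stats)  # p<0.01 and |delta|>0.5, both strict
        assert d.table["fragment_id"].tolist() == ["c", "a"]  # ranked by |t|
        assert d.table["direction"].tolist() == ["hyper", "hypo"]

    def test_ratio_scale_interpretation(self):
        stats = pd.DataFrame(
            {"fragment_id": ["a"], "delta": [0.55], "t": [5.0], "p_value": [1e-4]}
        )
        assert len(h.call_dmrs(stats, fold_change_scale="log")) == 1
        # |2^0.55 - 1| = 0.464 < 0.5 -> rejected on the ratio scale
        assert len(h.call_dmrs(stats, fold_change_scale="ratio")) == 0

    def test_empty_stats(self):
        empty = pd.DataFrame(columns=["fragment_id", "delta", "t", "p_value"])
        assert len(h.call_dmrs(empty)) == 0

    def test_null_calibration_before_effect_filter(self):
        """~1% of null loci pass p<0.01 when the effect filter is inactive."""
        rng = np.random.default_rng(13)
        df, groups = _matrix_from_groups(
            rng.normal(size=(1000, 12)), rng.normal(size=(1000, 14))
        )
        stats, _ = h.locus_differential_test(df, groups)
        d = h.call_dmrs(stats, p_threshold=0.01, delta_threshold=1e-9)
        sigma = np.sqrt(1000 * 0.01 * 0.99)
        assert abs(len(d) - 10) <= 3 * sigma

    def test_invariant_to_sample_column_order(self, small_processed):
        _sig, _st, matrix = small_processed
        stats, _ = h.locus_differential_test(matrix.values, matrix.groups)
        base = set(h.call_dmrs(stats).table["fragment_id"])
        rng = np.random.default_rng(14)
        perm = rng.permutation(matrix.values.columns)
        stats2, _ = h.locus_differential_test(matrix.values[perm], matrix.groups)
        assert set(h.call_dmrs(stats2).table["fragment_id"]) == base


class TestDirections:
    def test_all_positive_deltas(self):
        table = pd.DataFrame(
            {"fragment_id": ["a", "b"], "delta": [0.7, 1.0], "t": [3, 4], "p_value": [0.001] * 2}
        )
        assert h.summarize_directions(table)["hypo_fraction"] == 1.0

    def test_per_category_counts_conserve_total(self):
        rng = np.random.default_rng(15)
        n = 200
        table = pd.DataFrame(
            {
                "fragment_id": [f"f{i}" for i in range(n)],
                "delta": rng.normal(size=n),
                "t": rng.normal(size=n),
                "p_value": rng.uniform(size=n),
            }
        )
        cats = pd.Series(
            rng.choice(["intron", "exon", "promoter"], n),
            index=table["fragment_id"],
        )
        out = h.summarize_directions(table, cats)
        assert out["per_category"]["n"].sum() == out["n_dmrs"] == n
        assert out["n_hypo"] + out["n_hyper"] == n

    def test_empty_set_reports_missing_fraction(self):
        empty = pd.DataFrame(columns=["fragment_id", "delta", "t", "p_value"])
        assert np.isnan(h.summarize_directions(empty)["hypo_fraction"])


class TestClustering:
    def test_squared_euclidean_identity(self):
        d = _nan_sqeuclidean_condensed(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0] == pytest.approx(25.0)

    def test_missing_entries_pairwise_excluded(self):
        M = np.array([[0.0, np.nan, 1.0], [1.0, 5.0, 2.0]])
        # shared coords 0 and 2: ss = 1 + 1 = 2, rescaled by 3/2
        d = _nan_sqeuclidean_condensed(M)
        assert d[0] == pytest.approx(3.0)

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0.0, 0.3, size=(60, 12))
        b = rng.normal(2.0, 0.3, size=(60, 14))
        df, groups = _matrix_from_groups(a, b)
        stats, _ = h.locus_differential_test(df, groups)
        res = h.select_and_cluster_heatmap(df, stats, p_cut=1e-3, delta_cut=0.5)
        split = res.sample_bipartition()
        by_group = {
            g: set(split[groups[groups == g].index]) for g in ("control", "case")
        }
        assert by_group["control"].isdisjoint(by_group["case"])
        assert len(by_group["control"]) == 1 and len(by_group["case"]) == 1

    def test_too_few_selected_loci_raise(self):
        df, groups = _matrix_from_groups(
            np.random.default_rng(0).normal(size=(5, 3)), np.random.default_rng(1).normal(size=(5, 3))
        )
        stats, _ = h.locus_differential_test(df, groups)
        with pytest.raises(ValueError):
            h.select_and_cluster_heatmap(df, stats, p_cut=1e-12, delta_cut=99)


class TestVolcano:
    def test_exact_points_and_row_count(self):
        stats = pd.DataFrame(
            {
                "fragment_id": ["a", "b", "c"],
                "delta": [0.0, 1.0, -1.0],
                "t": [0.0, 2.0, -2.0],
                "p_value": [1.0, 0.25, 0.5],
            }
        )
        v = h.volcano_table(stats)
        assert len(v) == len(stats)
        assert v["neg_log2_p"].iloc[0] == 0.0
        assert v["neg_log2_p"].iloc[1] == pytest.approx(2.0)

    def test_zero_pvalue_floored(self):
        stats = pd.DataFrame(
            {"fragment_id": ["a"], "delta": [5.0], "t": [np.inf], "p_value": [0.0]}
        )
        v = h.volcano_table(stats)
        assert np.isfinite(v["neg_log2_p"].iloc[0])
        assert v["neg_log2_p"].iloc[0] == pytest.approx(-np.log2(1e-300))
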