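"""Concordance statistics and moderated-t differential expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenomask import (
    ExpressionMatrix,
    bh_adjust,
    group_means,
    moderated_t_test,
    msd_ranked,
    mva,
    pearson_summary,
    ranked_profile,
    signal_histogram,
)


def matrix_from(values, cols):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(values,
                         index=[f"tc{i:04d}" for i in range(values.shape[0])],
                         columns=cols)
    return ExpressionMatrix(frame, "log2")


class TestPearsonSummary:
    def test_comparison_counts_four_vs_four(self):
        rng = np.random.default_rng(0)
        cols = [f"BM{i}" for i in range(4)] + [f"SP{i}" for i in range(4)]
        m = matrix_from(rng.normal(8, 1, (100, 8)), cols)
        groups = {c: c[:2] for c in cols}
        report = pearson_summary(m, groups)
        n = dict(zip(report.summaries["pair"], report.summaries["n"]))
        assert n == {"BM-BM": 6, "SP-SP": 6, "BM-SP": 16}
        for row in report.summaries.itertuples():
            assert row.se == pytest.approx(row.sd / np.sqrt(row.n))

    def test_cross_counts_three_vs_eight(self):
        rng = np.random.default_rng(1)
        cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(8)]
        m = matrix_from(rng.normal(8, 1, (50, 11)), cols)
        report = pearson_summary(m, {c: c[0] for c in cols})
        n = dict(zip(report.summaries["pair"], report.summaries["n"]))
        assert n["a-b"] == 24

    def test_matrix_symmetric_unit_diagonal(self, log2_matrix):
        report = pearson_summary(log2_matrix,
                                 {s: "g" for s in log2_matrix.samples})
        corr = report.correlations
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_duplicated_sample_has_unit_correlation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(8, 1, 60)
        m = matrix_from(np.column_stack([base, base, rng.normal(8, 1, 60)]),
                        ["a1", "a2", "b1"])
        report = pearson_summary(m, {"a1": "a", "a2": "a", "b1": "b"})
        assert report.correlations.loc["a1", "a2"] == pytest.approx(1.0)

    def test_anticorrelated_samples(self):
        x = np.linspace(1, 5, 20)
        m = matrix_from(np.column_stack([x, -x]), ["u", "v"])
        report = pearson_summary(m, {"u": "g", "v": "g"})
        assert report.correlations.loc["u", "v"] == pytest.approx(-1.0)

    def test_zero_variance_sample_named_in_error(self):
        m = matrix_from(np.column_stack([np.ones(10), np.arange(10.0)]),
                        ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            pearson_summary(m, {"flat": "g", "ok": "g"})


class TestMvA:
    def test_identical_groups_give_zero_m(self):
        means = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        result = mva(means, means.copy())
        assert np.allclose(result.records["M"], 0.0)
        assert result.outlier_count == 0

    def test_exact_twofold_shift_counts_as_outlier(self):
        a = pd.Series([5.0, 6.0, 7.0], index=list("abc"))
        b = a.copy()
        b["b"] -= 1.0  # exactly 2-fold on log2 scale, inclusive boundary
        result = mva(a, b)
        assert result.outlier_count == 1
        assert result.records.loc["b", "M"] == pytest.approx(1.0)
        assert result.records.loc["b", "A"] == pytest.approx(5.5)

    def test_universe_mismatch_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            mva(a, b)

    def test_outliers_vanish_after_masking_contaminated_clusters(self, small_study):
        from xenomask import apply_mask, preprocess_pipeline
        clusters = preprocess_pipeline(small_study.probe_matrix,
                                       small_study.mapping)
        g = small_study.groups
        a = group_means(clusters, g, "ALL.100")
        b = group_means(clusters, g, "ALL.90")
        before = mva(a, b)
        outliers = set(before.records.index[before.records["M"].abs() >= 1.0])
        assert outliers <= set(small_study.truth.contaminated_clusters)
        masked = apply_mask(clusters, small_study.truth.contaminated_clusters)
        after = mva(group_means(masked, g, "ALL.100"),
                    group_means(masked, g, "ALL.90"))
        assert after.outlier_count == 0


class TestMsd:
    def test_identical_profiles_give_zero(self):
        ref = pd.Series(np.linspace(10, 2, 9), index=[f"c{i}" for i in range(9)])
        assert msd_ranked(ref, ref.copy()) == 0.0

    def test_constant_unit_offset_gives_one(self):
        ref = pd.Series(np.linspace(10, 2, 9), index=[f"c{i}" for i in range(9)])
        assert msd_ranked(ref, ref + 1.0) == pytest.approx(1.0)

    def test_invariant_to_cluster_reordering(self):
        rng = np.random.default_rng(3)
        ref = pd.Series(rng.normal(8, 2, 50), index=[f"c{i}" for i in range(50)])
        comp = ref + rng.normal(0, 0.5, 50)
        shuffled = comp.sample(frac=1.0, random_state=1)
        assert msd_ranked(ref, shuffled) == pytest.approx(msd_ranked(ref, comp))

    def test_ranked_profile_sorted_descending(self):
        ref = pd.Series([1.0, 3.0, 2.0], index=list("abc"))
        prof = ranked_profile(ref, ref * 0 + 1.0)
        assert list(prof.index) == ["b", "c", "a"]


class TestHistogram:
    def test_frequencies_sum_to_cluster_count(self, log2_matrix):
        groups = {s: ("g1" if i < 3 else "g2")
                  for i, s in enumerate(log2_matrix.samples)}
        freqs, edges = signal_histogram(log2_matrix, groups, bins=12)
        assert (freqs.sum(axis=1) == 30).all()
        assert len(edges) == 13

    def test_single_cluster_occupies_one_bin(self):
        m = matrix_from(np.array([[5.0, 5.0]]), ["a", "b"])
        freqs, _ = signal_histogram(m, {"a": "g", "b": "g"}, bins=5)
        assert (freqs.loc["g"] > 0).sum() == 1

    def test_host_samples_have_lighter_high_intensity_tail(self, small_study):
        # each group normalised within itself, as host-only arrays are in
        # practice; joint quantile normalisation would force the host
        # arrays onto the human-dominated common distribution
        from xenomask import preprocess_pipeline
        blocks = []
        for label in ("ALL.100", "NES"):
            cols = [s for s, g in small_study.groups.items() if g == label]
            blocks.append(preprocess_pipeline(
                small_study.probe_matrix.subset_samples(cols),
                small_study.mapping).values)
        clusters = ExpressionMatrix(pd.concat(blocks, axis=1), "log2")
        freqs, edges = signal_histogram(clusters, small_study.groups, bins=20)
        centres = (edges[:-1] + edges[1:]) / 2
        high = centres > 7.0
        assert freqs.loc["NES", high].sum() < freqs.loc["ALL.100", high].sum()


class TestBH:
    def test_hand_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_against_hand_rolled_step_up(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        order = np.argsort(p)
        n = len(p)
        adj_sorted = np.minimum.accumulate(
            (p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestModeratedT:
    def two_group_matrix(self, seed=5, n=200, shift=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(8, 1, size=(n, 8))
        X[: n // 10, :4] += shift
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        return matrix_from(X, cols), {c: c[0] for c in cols}

    def test_prior_df_zero_recovers_pooled_t(self):
        m, groups = self.two_group_matrix(shift=1.0)
        res = moderated_t_test(m, groups, "a", "b", prior_df=0.0)
        a = m.values.iloc[:, :4].to_numpy()
        b = m.values.iloc[:, 4:].to_numpy()
        expected = stats.ttest_ind(a, b, axis=1)
        assert res.table["t"].to_numpy() == pytest.approx(expected.statistic)
        assert res.table["p"].to_numpy() == pytest.approx(expected.pvalue)

    def test_prior_df_infinite_shares_common_variance(self):
        m, groups = self.two_group_matrix()
        res = moderated_t_test(m, groups, "a", "b", prior_df=np.inf)
        diff = m.values.iloc[:, :4].mean(axis=1) - m.values.iloc[:, 4:].mean(axis=1)
        scale = np.sqrt(res.prior_var * (1 / 4 + 1 / 4))
        assert res.table["t"].to_numpy() == pytest.approx((diff / scale).to_numpy())

    def test_adjusted_p_monotone_and_above_raw(self):
        m, groups = self.two_group_matrix(shift=2.0)
        res = moderated_t_test(m, groups, "a", "b")
        t = res.table.sort_values("p")
        assert (t["adj_p"].to_numpy() >= t["p"].to_numpy() - 1e-12).all()
        assert (np.diff(t["adj_p"].to_numpy()) >= -1e-12).all()
        assert ((t["adj_p"] >= 0) & (t["adj_p"] <= 1)).all()

    def test_zero_variance_cluster_moderated_not_degenerate(self):
        rng = np.random.default_rng(6)
        X = rng.normal(8, 1, size=(50, 8))
        X[0] = 8.0  # identical in every sample
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        m = matrix_from(X, cols)
        res = moderated_t_test(m, {c: c[0] for c in cols}, "a", "b")
        assert np.isfinite(res.table["t"].iloc[0])
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_small_group_rejected(self):
        m, groups = self.two_group_matrix()
        groups = dict(groups)
        groups["a1"] = groups["a2"] = groups["a3"] = "b"
        with pytest.raises(ValueError):
            moderated_t_test(m, groups, "a", "b")

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(7)
        X = rng.normal(8, 1, size=(1000, 8))
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        m = matrix_from(X, cols)
        res = moderated_t_test(m, {c: c[0] for c in cols}, "a", "b")
        frac = (res.table["adj_p"] < 0.05).mean()
        # binomial error bound at p=0.05, n=1000
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 1000)
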