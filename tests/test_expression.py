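import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnapipe import simdata
from pirnapipe.expression import (
    benjamini_hochberg,
    differential_features,
    mad_outlier_filter,
    mad_outlier_mask,
    per_gene_test,
    size_factors,
    tpm_normalize,
    zscore_cluster_matrix,
)
from pirnapipe.io import ExpressionMatrix


def _matrix(values, features=None, samples=None, conditions=None, unit="count"):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=samples)
    return ExpressionMatrix(df, conditions=conditions or {}, unit=unit)


class TestTpm:
    def test_single_feature(self):
        m = tpm_normalize(_matrix([[50.0]]))
        assert m.values.iloc[0, 0] == pytest.approx(1e6)

    def test_proportional_scaling(self):
        m = tpm_normalize(_matrix([[10.0], [30.0], [60.0]]))
        np.testing.assert_allclose(m.values["s0"].values, [1e5, 3e5, 6e5])

    def test_columns_sum_to_million(self, rng):
        m = tpm_normalize(_matrix(rng.integers(0, 500, (50, 4)) + 1))
        np.testing.assert_allclose(m.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_transcript_mode_matches_length_oracle(self):
        counts = np.array([[10.0, 20.0], [40.0, 10.0], [5.0, 5.0], [0.0, 8.0], [45.0, 7.0]])
        lengths = {"f0": 100.0, "f1": 200.0, "f2": 50.0, "f3": 400.0, "f4": 250.0}
        m = tpm_normalize(_matrix(counts), lengths=lengths)
        # oracle: rate = count/length, then per-million scale, per column
        lens = np.array([lengths[f"f{i}"] for i in range(5)])
        rate = counts / lens[:, None]
        want = rate / rate.sum(axis=0) * 1e6
        np.testing.assert_allclose(m.values.values, want)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize(_matrix([[0.0, 1.0], [0.0, 2.0]]))


class TestSizeFactors:
    def test_doubled_sample_ratio_two(self, rng):
        a = rng.integers(10, 500, 100).astype(float)
        df = pd.DataFrame({"A": a, "B": 2 * a})
        sf = size_factors(df)
        assert sf["B"] / sf["A"] == pytest.approx(2.0)


class TestDifferentialFeatures:
    def test_identical_counts_unchanged(self):
        counts = np.tile([[100.0], [50.0], [10.0]], (1, 6))
        cond = {f"s{j}": ("control" if j < 3 else "KD") for j in range(6)}
        results = differential_features(_matrix(counts, conditions=cond))
        for r in results:
            assert r.log2_fold_change == pytest.approx(0.0)
            assert r.call == "unchanged"

    def test_requires_two_conditions_with_replicates(self):
        counts = np.ones((5, 3))
        cond = {"s0": "a", "s1": "a", "s2": "b"}
        with pytest.raises(ValueError):
            differential_features(_matrix(counts, conditions=cond))

    def test_planted_fourfold_recovered_single_seed(self):
        cfg = simdata.SimulationConfig(seed=11, n_genes=201, targeted_fraction=0.0,
                                       expr_mean=500.0, expr_log_sigma=0.0,
                                       nb_dispersion=0.1, kd_effect_mean=2.0)
        matrix, truth = simdata.make_expression(cfg, targeted_ids=["gene_00001"])
        results = {r.feature_id: r for r in differential_features(matrix)}
        assert results["gene_00001"].call == "up"

    def test_pure_null_type_one_error_controlled(self):
        # fraction of null features with padj <= 0.05 must stay within
        # 1.5x the nominal level over 100 seeds
        fractions = []
        for seed in range(100):
            cfg = simdata.SimulationConfig(
                seed=5000 + seed, n_genes=200, targeted_fraction=0.0,
                expr_mean=300.0, expr_log_sigma=0.5, nb_dispersion=0.1,
                kd_effect_mean=0.0,
            )
            matrix, _ = simdata.make_expression(cfg, targeted_ids=[])
            results = differential_features(matrix)
            fractions.append(np.mean([r.padj <= 0.05 for r in results]))
        assert float(np.mean(fractions)) <= 1.5 * 0.05

    def test_call_invariant(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(10, 1000, (80, 6)).astype(float)
        cond = {f"s{j}": ("control" if j < 3 else "KD") for j in range(6)}
        for r in differential_features(_matrix(counts, conditions=cond)):
            if r.call == "up":
                assert r.padj <= 0.05 and r.log2_fold_change >= 1
            elif r.call == "down":
                assert r.padj <= 0.05 and r.log2_fold_change <= -1


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        p = rng.random(200)
        from statsmodels.stats.multitest import multipletests

        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), expected)


class TestMadRule:
    def test_spec_example_removes_only_outlier(self):
        # hand oracle: median 1.05, |x - median| = [.05, .05, .15, 0, 6.95],
        # MAD = .05, scaled = .07413, 3x = .22239 -> only 8 exceeds
        keep = mad_outlier_mask([1, 1.1, 0.9, 1.05, 8])
        np.testing.assert_array_equal(keep, [True, True, True, True, False])

    def test_constant_vector_nothing_removed(self):
        keep = mad_outlier_mask([2.0] * 6)
        assert keep.all()

    def test_strict_inequality_at_boundary(self):
        # construct values where one point sits at exactly 3 scaled MADs
        x = np.array([0.0, -1.0, 1.0, -1.0, 1.0])
        scaled_mad = 1.4826 * np.median(np.abs(x - np.median(x)))
        x = np.append(x, 3 * scaled_mad)  # exactly at the boundary of the original center?
        # recompute on the final vector: boundary point must NOT be removed
        med = np.median(x)
        smad = 1.4826 * np.median(np.abs(x - med))
        boundary = med + 3 * smad
        x[-1] = boundary
        keep = mad_outlier_mask(x)
        assert keep[-1]

    def test_zero_mad_removes_any_deviation(self):
        keep = mad_outlier_mask([5.0, 5.0, 5.0, 5.0, 7.0])
        np.testing.assert_array_equal(keep, [True, True, True, True, False])

    def test_affine_equivariance(self, rng):
        x = rng.normal(0, 1, 20)
        x[3] = 25.0
        base = mad_outlier_mask(x)
        for a, b in [(2.0, 5.0), (-3.0, 1.0), (0.5, -10.0)]:
            np.testing.assert_array_equal(mad_outlier_mask(a * x + b), base)

    def test_permutation_invariance(self, rng):
        x = rng.normal(0, 1, 15)
        x[0] = 40.0
        perm = rng.permutation(15)
        keep = mad_outlier_mask(x)
        keep_perm = mad_outlier_mask(x[perm])
        np.testing.assert_array_equal(keep_perm, keep[perm])

    def test_filter_flags_underpopulated_features(self):
        df = pd.DataFrame(
            [[1.0, 1.1, 0.9, 1.05, 8.0, 1.02], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
            index=["g1", "g2"],
        )
        masked, excluded = mad_outlier_filter(df, min_values=4)
        assert masked.loc["g1"].isna().sum() == 1
        assert not excluded["g1"] and not excluded["g2"]


class TestPerGeneTest:
    def test_equal_means_f_near_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], index=["g"])
        cond = {c: ("a" if i < 3 else "b") for i, c in enumerate(df.columns)}
        res = per_gene_test(df, cond)
        assert res.loc["g", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["g", "p"] == pytest.approx(1.0)

    def test_textbook_anova(self):
        # closed-form oracle: groups (1,2,3), (2,3,4), (5,6,7)
        g = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([5.0, 6, 7])]
        k, n = 3, 9
        grand = np.concatenate(g).mean()
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in g)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in g)
        f_oracle = (ssb / (k - 1)) / (ssw / (n - k))
        p_oracle = stats.f.sf(f_oracle, k - 1, n - k)
        df = pd.DataFrame([np.concatenate(g)], index=["g"])
        cond = {c: f"grp{i // 3}" for i, c in enumerate(df.columns)}
        res = per_gene_test(df, cond)
        assert res.loc["g", "F"] == pytest.approx(f_oracle, rel=1e-6)
        assert res.loc["g", "p"] == pytest.approx(p_oracle, rel=1e-6)

    def test_two_group_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 5)
        df = pd.DataFrame([np.concatenate([a, b])], index=["g"])
        cond = {c: ("a" if i < 4 else "b") for i, c in enumerate(df.columns)}
        res = per_gene_test(df, cond)
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert res.loc["g", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.loc["g", "p"] == pytest.approx(p_t, rel=1e-10)

    def test_degenerate_p_one(self):
        df = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["g"])
        cond = {c: ("a" if i < 2 else "b") for i, c in enumerate(df.columns)}
        res = per_gene_test(df, cond)
        assert res.loc["g", "p"] == 1.0


class TestZscoreKmeans:
    def test_rows_standardized(self, rng):
        df = pd.DataFrame(rng.normal(3, 2, (10, 6)))
        z, _ = zscore_cluster_matrix(df, k=2, seed=0)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_constant_row_zeroed(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        z, _ = zscore_cluster_matrix(df, k=1, seed=0)
        np.testing.assert_array_equal(z.iloc[0].values, 0.0)

    def test_planted_partition_recovered(self, rng):
        up = np.tile([1.0, 1.0, 1.0, 5.0, 5.0, 5.0], (15, 1)) + rng.normal(0, 0.05, (15, 6))
        down = np.tile([5.0, 5.0, 5.0, 1.0, 1.0, 1.0], (15, 1)) + rng.normal(0, 0.05, (15, 6))
        df = pd.DataFrame(np.vstack([up, down]))
        _, labels = zscore_cluster_matrix(df, k=2, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, labels.values) == 1.0

    def test_k_bounds(self):
        df = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError):
            zscore_cluster_matrix(df, k=5)
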