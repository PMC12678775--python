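import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from metadiet.omicsprep import (
    block_normalize,
    bray_curtis,
    clr_transform,
    impute_and_filter,
    inverse_normal_metabolites,
    pcoa_outlier_flag,
    prevalence_filter,
    process_metabolites,
    shannon_index,
)


class TestBlockNormalize:
    def test_single_day_median_scaled_to_one(self):
        m = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out = block_normalize(m, [0, 0, 0])
        assert np.allclose(out["a"], [0.5, 1.0, 1.5])

    def test_idempotent_on_median_one_data(self):
        m = pd.DataFrame({"a": [0.5, 1.0, 1.5], "b": [0.9, 1.0, 1.1]})
        out = block_normalize(m, [0, 0, 0])
        pd.testing.assert_frame_equal(out, m)

    def test_multiplicative_day_drift_removed(self):
        rng = np.random.default_rng(0)
        day1 = rng.lognormal(0, 0.5, 100)
        m = pd.DataFrame({"a": np.concatenate([day1, day1 * 2.0])})
        days = [0] * 100 + [1] * 100
        out = block_normalize(m, days)
        a, b = out["a"][:100].to_numpy(), out["a"][100:].to_numpy()
        assert np.allclose(np.sort(a), np.sort(b))

    def test_cross_day_median_close_to_one(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.lognormal(0, 1, (64, 5)),
                         columns=list("abcde"))
        days = np.arange(64) % 8
        out = block_normalize(m, days)
        for _, idx in out.groupby(days).groups.items():
            med = out.loc[idx].median()
            assert np.allclose(med, 1.0, atol=1e-9)

    def test_all_missing_day_stays_missing(self):
        m = pd.DataFrame({"a": [np.nan, np.nan, 1.0, 2.0]})
        out = block_normalize(m, [0, 0, 1, 1])
        assert out["a"].isna().tolist() == [True, True, False, False]


class TestImputeAndFilter:
    def test_minimum_imputation_below_bound(self):
        col = [0.3, 1.0, 2.0, np.nan] + [1.0] * 6  # 10% missing
        m = pd.DataFrame({"a": col})
        out, dropped = impute_and_filter(m)
        assert dropped == []
        assert out["a"].iloc[3] == pytest.approx(0.3)

    def test_exclusion_above_bound(self):
        m = pd.DataFrame({"a": [np.nan] * 25 + [1.0] * 75,
                          "b": np.ones(100)})
        out, dropped = impute_and_filter(m)
        assert dropped == ["a"] and list(out.columns) == ["b"]

    def test_exactly_at_bound_is_excluded(self):
        m = pd.DataFrame({"a": [np.nan, 1.0, 2.0, 3.0, 4.0]})  # 20%
        out, dropped = impute_and_filter(m, max_missing_frac=0.20)
        assert dropped == ["a"]

    def test_fully_observed_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, dropped = impute_and_filter(m)
        pd.testing.assert_frame_equal(out, m)


class TestInverseNormal:
    def test_constant_metabolite_dropped_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            out = inverse_normal_metabolites(m)
        assert list(out.columns) == ["b"]

    def test_canonical_order_output_is_standardish(self, small_cohorts):
        disc, _ = small_cohorts
        out, dropped = process_metabolites(disc.metabolites_raw, disc.run_day)
        assert not out.isna().any().any()
        # ties from minimum imputation shift means slightly off zero
        assert np.abs(out.mean()).max() < 0.05


class TestPrevalenceFilter:
    def test_strictly_greater_than_bound(self):
        n = 100
        m = pd.DataFrame({
            "exactly10": [1.0] * 10 + [0.0] * 90,
            "eleven": [1.0] * 11 + [0.0] * 89,
            "zero": [0.0] * n,
        })
        out = prevalence_filter(m, min_prev=0.10)
        assert list(out.columns) == ["eleven"]


class TestCLR:
    def test_uniform_composition_maps_to_zero(self):
        m = pd.DataFrame([[0.25, 0.25, 0.25, 0.25]])
        assert np.allclose(clr_transform(m).to_numpy(), 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        m = rng.dirichlet(np.ones(6), size=20)
        out = clr_transform(pd.DataFrame(m))
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_geometric_mean_arithmetic(self):
        m = pd.DataFrame([[0.5, 0.25, 0.25]])
        out = clr_transform(m).to_numpy()[0]
        assert np.allclose(out, [0.4621, -0.2310, -0.2310], atol=1e-4)

    def test_matches_reference_clr_on_positive_data(self):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        rng = np.random.default_rng(1)
        m = rng.dirichlet(np.ones(5), size=10)
        ours = clr_transform(pd.DataFrame(m)).to_numpy()
        theirs = skbio_comp.clr(m)
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(pd.DataFrame([[0.5, -0.1, 0.6]]))


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert shannon_index([0.25] * 4) == pytest.approx(np.log(4))

    def test_single_species_zero(self):
        assert shannon_index([1.0, 0.0, 0.0]) == 0.0

    def test_direct_formula(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_uniform_maximises_entropy(self):
        rng = np.random.default_rng(2)
        base = shannon_index(np.full(6, 1 / 6))
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            assert shannon_index(p) <= base + 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])


class TestBrayCurtis:
    def test_examples(self):
        m = np.array([[2.0, 0.0, 4.0], [0.0, 2.0, 2.0]])
        D = bray_curtis(m)
        assert D[0, 1] == pytest.approx(0.6)
        assert bray_curtis(np.array([[1.0, 2.0], [1.0, 2.0]]))[0, 1] == 0.0
        assert bray_curtis(np.array([[1.0, 0.0], [0.0, 3.0]]))[0, 1] == 1.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.random((12, 7))
        D = bray_curtis(m)
        for i in range(12):
            for j in range(i + 1, 12):
                assert D[i, j] == pytest.approx(
                    scipy_braycurtis(m[i], m[j]), abs=1e-12
                )

    def test_metric_properties_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = rng.random((8, 5)) * rng.integers(0, 2, (8, 5))
            m[m.sum(axis=1) == 0, 0] = 0.5
            D = bray_curtis(m)
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0.0)
            assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()

    def test_two_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


class TestPcoaOutliers:
    def _dist(self, X):
        from scipy.spatial.distance import cdist

        return cdist(X, X)

    def test_single_tight_cluster_unflagged(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.1, (30, 3))
        flags = pcoa_outlier_flag(self._dist(X))
        assert not flags.any()

    def test_far_point_flagged(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 0.1, (30, 3))
        X[-1] = [50.0, 50.0, 50.0]
        flags = pcoa_outlier_flag(self._dist(X))
        assert flags.iloc[-1]
        assert flags.sum() == 1

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 4))
        D = self._dist(X)
        a = pcoa_outlier_flag(D)
        b = pcoa_outlier_flag(D)
        assert (a == b).all()

    def test_tiny_input_not_flagged(self):
        D = np.zeros((3, 3))
        assert not pcoa_outlier_flag(D).any()
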