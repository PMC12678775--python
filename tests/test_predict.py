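import numpy as np
import pandas as pd
import pytest

from metadiet.predict import (
    boruta_select,
    bootstrap_auc_compare,
    build_panel,
    delong_test,
    evaluate,
    mean_mask_rfe,
    permutation_importance,
    quartile_labels,
    tune_and_fit,
    twin_aware_split,
)


class TestQuartileLabels:
    def test_one_to_eight(self):
        s = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        lab = quartile_labels(s)
        assert set(lab.index[lab == 0]) == {"a", "b"}
        assert set(lab.index[lab == 1]) == {"g", "h"}
        assert len(lab) == 4

    def test_quarter_per_class_at_n100(self):
        s = pd.Series(np.random.default_rng(0).normal(size=100))
        lab = quartile_labels(s)
        assert (lab == 0).sum() == 25 and (lab == 1).sum() == 25

    def test_ties_resolved_deterministically(self):
        s = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 4.0, 4.0])
        a = quartile_labels(s)
        b = quartile_labels(s)
        pd.testing.assert_series_equal(a, b)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            quartile_labels(pd.Series(np.ones(20)))


def _labels_families(n=120, seed=0, frac_paired=0.5):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    labels = pd.Series(rng.integers(0, 2, n), index=ids)
    fam = []
    fid = 0
    i = 0
    while i < n:
        if rng.random() < frac_paired and i + 1 < n:
            fam += [f"f{fid}", f"f{fid}"]
            i += 2
        else:
            fam.append(f"f{fid}")
            i += 1
        fid += 1
    return labels, pd.Series(fam[:n], index=ids)


class TestTwinAwareSplit:
    def test_families_never_straddle_and_classes_balance(self):
        labels, fams = _labels_families()
        plan = twin_aware_split(labels, fams, seed=1)
        plan.validate(labels)
        train_lab = labels.loc[plan.train_ids]
        test_lab = labels.loc[plan.test_ids]
        assert train_lab.value_counts().nunique() == 1
        assert test_lab.value_counts().nunique() == 1

    def test_large_family_lands_on_one_side(self):
        n = 60
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series([0, 1] * 30, index=ids)
        fams = pd.Series(["big"] * 18 + [f"f{i}" for i in range(n - 18)],
                         index=ids)
        plan = twin_aware_split(labels, fams, seed=0)
        sides = [set(plan.train_ids), set(plan.test_ids)]
        big = {i for i in ids[:18] if any(i in s for s in sides)}
        assert big <= sides[0] or big <= sides[1]

    def test_same_seed_is_identical(self):
        labels, fams = _labels_families(seed=5)
        a = twin_aware_split(labels, fams, seed=9)
        b = twin_aware_split(labels, fams, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_tiny_class_rejected(self):
        ids = [f"s{i}" for i in range(12)]
        labels = pd.Series([1] + [0] * 11, index=ids)
        fams = pd.Series(ids, index=ids)
        with pytest.raises(ValueError):
            twin_aware_split(labels, fams, seed=0)


class TestBoruta:
    def test_target_copy_of_feature_confirmed(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((150, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = (X["f2"] > 0).astype(int).to_numpy()
        confirmed, hits = boruta_select(X, y, max_iter=40, n_estimators=32,
                                        seed=0)
        assert "f2" in confirmed

    def test_planted_features_found_and_noise_rejected(self):
        rng = np.random.default_rng(1)
        n, p = 250, 20
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"f{i}" for i in range(p)])
        signal = X["f0"] + X["f1"] - X["f2"]
        y = (signal + 0.3 * rng.standard_normal(n) > 0).astype(int).to_numpy()
        confirmed, _ = boruta_select(X, y, max_iter=60, n_estimators=48,
                                     seed=1)
        assert {"f0", "f1", "f2"} <= set(confirmed)
        noise_confirmed = [f for f in confirmed if f not in {"f0", "f1", "f2"}]
        assert len(noise_confirmed) <= 2

    def test_single_feature_rejected(self):
        X = pd.DataFrame({"only": np.arange(10.0)})
        with pytest.raises(ValueError):
            boruta_select(X, np.arange(10) % 2)


class TestTuneAndFit:
    def _data(self, seed=0, n=120):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.standard_normal((n, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = (X["f0"] + 0.3 * rng.standard_normal(n) > 0).astype(int).to_numpy()
        return X, y

    def test_single_cell_grid_chosen(self):
        X, y = self._data()
        cell = {"mtry": "sqrt", "min_node": 5, "split_rule": "gini"}
        _, best, table = tune_and_fit(X, y, grid=[cell], cv_repeats=1,
                                      n_estimators=50, seed=0)
        assert best == cell and len(table) == 1

    def test_tie_breaks_to_first_grid_cell(self):
        X, y = self._data()
        cell = {"mtry": "sqrt", "min_node": 5, "split_rule": "gini"}
        _, best, table = tune_and_fit(X, y, grid=[cell, dict(cell)],
                                      cv_repeats=1, n_estimators=50, seed=0)
        assert table["cv_score"].iloc[0] == table["cv_score"].iloc[1]
        assert best is not table.iloc[1]

    def test_planted_signal_beats_chance(self):
        X, y = self._data(seed=3, n=200)
        _, _, table = tune_and_fit(
            X, y, grid=[{"mtry": "sqrt", "min_node": 5, "split_rule": "gini"}],
            cv_repeats=2, n_estimators=100, seed=0,
        )
        acc = table["cv_score"].iloc[0]
        se = np.sqrt(0.25 / 200)
        assert acc > 0.5 + 3 * se

    def test_empty_grid_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError):
            tune_and_fit(X, y, grid=[])


class _FrozenProbModel:
    """Deterministic stand-in model emitting a fixed column's value."""

    def __init__(self, col=0):
        self.col = col

    def predict_proba(self, X):
        p = np.clip(np.asarray(X)[:, self.col], 0, 1)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return np.asarray(X)[:, self.col]


class TestEvaluate:
    def test_concordant_pair_enumeration(self):
        X = pd.DataFrame({"p": [0.9, 0.8, 0.3, 0.1]})
        y = np.array([1, 0, 1, 0])
        res = evaluate(_FrozenProbModel(), X, y, n_boot=50, seed=0)
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        X = pd.DataFrame({"p": [0.9, 0.8, 0.3, 0.1]})
        y = np.array([1, 1, 0, 0])
        res = evaluate(_FrozenProbModel(), X, y, n_boot=50, seed=0)
        assert res.auc == 1.0

    def test_null_predictions_near_half(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"p": rng.random(500)})
        y = rng.integers(0, 2, 500)
        res = evaluate(_FrozenProbModel(), X, y, n_boot=200, seed=0)
        assert res.auc_ci[0] < 0.5 < res.auc_ci[1]

    def test_single_class_rejected(self):
        X = pd.DataFrame({"p": [0.9, 0.8]})
        with pytest.raises(ValueError):
            evaluate(_FrozenProbModel(), X, np.array([1, 1]), n_boot=10)


class TestDeLong:
    def test_identical_classifiers_p_one(self):
        rng = np.random.default_rng(1)
        probs = rng.random(100)
        labels = rng.integers(0, 2, 100)
        with pytest.warns(UserWarning):
            _, _, p = delong_test(probs, probs, labels)
        assert p == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        a = labels * 0.5 + rng.random(200) * 0.5
        b = rng.random(200)
        _, _, pab = delong_test(a, b, labels)
        _, _, pba = delong_test(b, a, labels)
        assert pab == pytest.approx(pba)

    def test_strong_vs_null_is_significant(self):
        rng = np.random.default_rng(3)
        labels = np.repeat([0, 1], 100)
        strong = labels + rng.normal(0, 0.3, 200)
        null = rng.random(200)
        auc_a, auc_b, p = delong_test(strong, null, labels)
        assert auc_a > 0.9 and p < 0.01


class TestBootstrapAucCompare:
    def test_identical_sets_p_one(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([0, 1], 50)
        probs = labels * 0.6 + rng.random(100) * 0.4
        p, obs, _ = bootstrap_auc_compare(probs, labels, probs, labels,
                                          n_boot=200, seed=0)
        assert obs == 0.0 and p == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        la = np.repeat([0, 1], 60)
        pa = la * 0.7 + rng.random(120) * 0.5
        lb = np.repeat([0, 1], 60)
        pb = rng.random(120)
        p1, *_ = bootstrap_auc_compare(pa, la, pb, lb, n_boot=300, seed=42)
        p2, *_ = bootstrap_auc_compare(pa, la, pb, lb, n_boot=300, seed=42)
        assert p1 == p2

    def test_small_b_warns(self):
        labels = np.repeat([0, 1], 20)
        probs = labels * 0.8 + 0.1
        with pytest.warns(UserWarning):
            bootstrap_auc_compare(probs, labels, probs, labels, n_boot=50)


class TestPermutationImportance:
    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(6)
        from sklearn.ensemble import RandomForestClassifier

        X = pd.DataFrame(rng.standard_normal((200, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = (X["f3"] > 0).astype(int).to_numpy()
        model = RandomForestClassifier(n_estimators=100, random_state=0)
        model.fit(X.to_numpy(), y)
        imp = permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert imp.index[0] == "f3"
        assert imp.iloc[0] > 0.1
        # the unused features sit at permutation-noise level
        assert np.abs(imp.iloc[1:]).max() < 0.05


class TestMeanMaskRfe:
    def _setup(self):
        rng = np.random.default_rng(7)
        from sklearn.ensemble import RandomForestClassifier

        cols = [f"f{i}" for i in range(12)]
        X = pd.DataFrame(rng.standard_normal((600, 12)), columns=cols)
        # each planted feature individually load-bearing: moderate noise so
        # masking any one of them costs a visible slice of AUC
        y = ((X["f0"] + X["f1"] + X["f2"]) / np.sqrt(3)
             + 0.75 * rng.standard_normal(600) > 0).astype(int).to_numpy()
        model = RandomForestClassifier(n_estimators=150, random_state=0)
        Xtr, ytr = X.iloc[:350], y[:350]
        Xte, yte = X.iloc[350:], y[350:]
        model.fit(Xtr.to_numpy(), ytr)
        imp = permutation_importance(model, Xtr, ytr, n_repeats=5, seed=0)
        return model, Xtr, Xte, yte, imp

    def test_step_zero_equals_unmasked_evaluation(self):
        model, Xtr, Xte, yte, imp = self._setup()
        res = mean_mask_rfe(model, Xtr.mean(), {"test": (Xte, yte)},
                            list(imp.index))
        ev = evaluate(model, Xte, yte, n_boot=10, seed=0)
        assert res.trajectory["metric_test"].iloc[0] == pytest.approx(ev.auc)

    def test_planted_features_survive_masking(self):
        model, Xtr, Xte, yte, imp = self._setup()
        res = mean_mask_rfe(model, Xtr.mean(), {"test": (Xte, yte)},
                            list(imp.index))
        assert {"f0", "f1", "f2"} <= set(res.selected_features)
        assert len(res.selected_features) <= 6
        final_auc = res.trajectory["metric_test"].iloc[-1]
        assert final_auc < res.original_metrics["test"] - 0.05

    def test_negative_tolerance_rejected(self):
        model, Xtr, Xte, yte, imp = self._setup()
        with pytest.raises(ValueError):
            mean_mask_rfe(model, Xtr.mean(), {"t": (Xte, yte)},
                          list(imp.index), tolerance=-0.1)


class TestBuildPanel:
    def test_union_and_covariate_exclusion(self):
        from metadiet.predict import RFEResult

        def _r(feats):
            return RFEResult(feats, pd.DataFrame(), feats, 0.05)

        panel = build_panel([_r(["a", "b", "age"]), _r(["b", "c"])])
        assert panel == ["a", "b", "c"]

    def test_single_model_identity(self):
        from metadiet.predict import RFEResult

        r = RFEResult(["m1", "m2"], pd.DataFrame(), ["m1", "m2"], 0.05)
        assert build_panel([r]) == ["m1", "m2"]
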