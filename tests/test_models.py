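import math

import numpy as np
import pandas as pd
import pytest

from anxio.models import (ClassifierConfig, EvaluationReport, KernelDensityNB,
                          ModelCandidate, ModelDegeneracyError, cohens_kappa,
                          default_configs, kfold_cv, landis_koch_band,
                          per_class_rates, roc_curves, save_model, load_model,
                          select_models, sequential_forward_selection, train)

import oracles


def blobs(n_per_class=60, sep=6.0, n_features=4, seed=0, classes=("low", "high")):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(classes):
        X.append(rng.normal(i * sep, 1.0, size=(n_per_class, n_features)))
        y += [c] * n_per_class
    return pd.DataFrame(np.vstack(X), columns=[f"f{j}" for j in range(n_features)]), np.array(y)


class TestKappa:
    def test_worked_example(self):
        res = cohens_kappa([[45, 5], [10, 40]])
        assert res.value == pytest.approx(0.70)
        assert res.band == "substantial"

    def test_diagonal_is_perfect(self):
        res = cohens_kappa(np.diag([10, 20, 30]))
        assert res.value == pytest.approx(1.0)
        assert res.band == "almost perfect"

    def test_chance_agreement_is_zero(self):
        assert cohens_kappa([[25, 25], [25, 25]]).value == pytest.approx(0.0)

    def test_degenerate_single_cell(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = cohens_kappa([[50, 0], [0, 0]])
        assert res.value == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force(self, trial):
        rng = np.random.default_rng(trial)
        M = rng.integers(1, 40, size=(3, 3))
        assert cohens_kappa(M).value == pytest.approx(
            oracles.cohens_kappa_reference(M.tolist()), rel=1e-12)

    def test_landis_koch_boundaries(self):
        assert landis_koch_band(-0.1) == "no agreement"
        assert landis_koch_band(0.20) == "slight"
        assert landis_koch_band(0.21) == "fair"
        assert landis_koch_band(0.40) == "fair"
        assert landis_koch_band(0.60) == "moderate"
        assert landis_koch_band(0.61) == "substantial"
        assert landis_koch_band(0.80) == "substantial"
        assert landis_koch_band(0.81) == "almost perfect"


class TestRates:
    def test_recall_rows(self):
        rates = per_class_rates([[45, 5], [10, 40]], ["high", "low"])
        assert rates["high"] == pytest.approx(0.90)
        assert rates["low"] == pytest.approx(0.80)

    def test_diagonal_all_ones(self):
        rates = per_class_rates(np.diag([5, 5, 5]), ["low", "medium", "high"])
        assert all(v == 1.0 for v in rates.values())

    def test_empty_class_is_nan(self):
        rates = per_class_rates([[0, 0], [1, 9]], ["high", "low"])
        assert math.isnan(rates["high"])


class TestRoc:
    def test_perfect_scores(self):
        y = np.array(["high"] * 5 + ["low"] * 5)
        scores = pd.DataFrame({"high": [1.0] * 5 + [0.0] * 5,
                               "low": [0.0] * 5 + [1.0] * 5})
        roc = roc_curves(y, scores)
        assert roc["high"]["auc"] == pytest.approx(1.0)
        assert roc["low"]["auc"] == pytest.approx(1.0)

    def test_label_independent_scores_near_chance(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            y = rng.permutation(np.array(["high"] * 50 + ["low"] * 50))
            s = rng.random(100)
            scores = pd.DataFrame({"high": s, "low": 1 - s})
            aucs.append(roc_curves(y, scores)["high"]["auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_three_class_emits_three_curves(self):
        y = np.array(["low", "medium", "high"] * 10)
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.random((30, 3)), columns=["low", "medium", "high"])
        assert len(roc_curves(y, scores)) == 3


class TestTrain:
    @pytest.mark.parametrize("config", default_configs(),
                             ids=lambda c: c.name)
    def test_separable_blobs_fit_well(self, config):
        X, y = blobs(seed=3)
        model = train(config, X, y, seed=0)
        acc = np.mean(model.predict(X) == y)
        assert acc >= 0.95

    def test_knn1_self_prediction_perfect(self):
        X, y = blobs(sep=1.0, seed=4)
        model = train(ClassifierConfig("knn", {"k": 1}), X, y, seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_rejected(self):
        X, _ = blobs(seed=5)
        with pytest.raises(ValueError, match="two classes"):
            train(ClassifierConfig("lda"), X, np.array(["low"] * len(X)), seed=0)

    def test_qda_degeneracy_message(self):
        X, y = blobs(n_per_class=3, n_features=5, seed=6)
        with pytest.raises(ModelDegeneracyError, match="reg_param"):
            train(ClassifierConfig("qda"), X, y, seed=0)

    def test_registry_has_nine_configs(self):
        assert len(default_configs()) == 9

    def test_kde_naive_bayes_recovers_blobs(self):
        X, y = blobs(seed=7)
        nb = KernelDensityNB().fit(X.to_numpy(), y)
        assert np.mean(nb.predict(X.to_numpy()) == y) >= 0.95
        proba = nb.predict_proba(X.to_numpy())
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_model_roundtrip(self, tmp_path):
        X, y = blobs(seed=8)
        model = train(ClassifierConfig("bagged_trees", {"n_learners": 30}), X, y, seed=0)
        save_model(model, tmp_path / "m.joblib")
        loaded = load_model(tmp_path / "m.joblib")
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
        assert loaded.feature_names == model.feature_names


class TestCrossValidation:
    def test_separable_data_near_perfect(self):
        X, y = blobs(seed=9)
        rep = kfold_cv(ClassifierConfig("bagged_trees", {"n_learners": 30}),
                       X, y, seed=0)
        assert rep.accuracy >= 0.97
        assert rep.kappa >= 0.9

    def test_pure_noise_near_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
            y = np.array(["low", "high"] * 50)
            rep = kfold_cv(ClassifierConfig("lda"), X, y, seed=seed)
            accs.append(rep.accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_permuted_labels_kappa_near_zero(self):
        X, y = blobs(seed=10)
        kappas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rep = kfold_cv(ClassifierConfig("bagged_trees", {"n_learners": 30}),
                           X, rng.permutation(y), seed=seed)
            kappas.append(rep.kappa)
        assert abs(np.mean(kappas)) < 0.1

    def test_loo_fold_arithmetic(self):
        X, y = blobs(n_per_class=5, seed=11)
        rep = kfold_cv(ClassifierConfig("knn", {"k": 1}), X, y, k=10, seed=0)
        assert rep.n_obs == 10

    def test_small_class_warns(self):
        X, y = blobs(seed=12)
        y = y.copy()
        y[:3] = "medium"
        y[3:60] = "low"
        with pytest.warns(UserWarning, match="members"):
            kfold_cv(ClassifierConfig("lda"), X, y, k=10, seed=0)

    def test_report_self_consistency(self):
        X, y = blobs(seed=13)
        rep = kfold_cv(ClassifierConfig("decision_tree", {"max_splits": 100}),
                       X, y, seed=0)
        again = rep.recompute()
        assert again.accuracy == rep.accuracy
        assert again.kappa == rep.kappa
        assert again.true_rates == rep.true_rates
        assert np.trace(rep.confusion) == pytest.approx(rep.accuracy * rep.n_obs)

    def test_grouped_cv_runs(self):
        X, y = blobs(seed=14)
        groups = np.repeat(np.arange(12), 10)
        rep = kfold_cv(ClassifierConfig("lda"), X, y, k=5, seed=0, groups=groups)
        assert rep.n_obs == len(y)


class TestFeatureSelection:
    def test_informative_feature_found_first(self):
        rng = np.random.default_rng(0)
        n = 120
        y = np.array(["low", "high"] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        X["f7"] = (y == "high") * 4.0 + rng.normal(size=n)
        selected = sequential_forward_selection(ClassifierConfig("lda"), X, y, seed=0)
        assert selected and selected[0] == "f7"

    def test_all_noise_selects_little(self):
        stops = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
            y = np.array(["low", "high"] * 40)
            sel = sequential_forward_selection(ClassifierConfig("lda"), X, y, seed=seed)
            stops += len(sel) <= 1
        assert stops >= 6  # chance plateau in the clear majority of runs

    def test_duplicated_feature_not_selected_twice(self):
        rng = np.random.default_rng(3)
        n = 120
        y = np.array(["low", "high"] * (n // 2))
        info = (y == "high") * 4.0 + rng.normal(size=n)
        X = pd.DataFrame({"a": info, "b": info.copy(),
                          "c": rng.normal(size=n)})
        sel = sequential_forward_selection(ClassifierConfig("lda"), X, y, seed=0)
        assert not ({"a", "b"} <= set(sel))


class TestModelSelection:
    def _candidate(self, acc, rates, n_feat):
        classes = tuple(rates)
        M = np.diag([int(100 * r) for r in rates.values()])
        rep = EvaluationReport(classes=classes, confusion=M, accuracy=acc,
                               true_rates=rates, precision=rates,
                               kappa=0.5, kappa_band="moderate")
        return ModelCandidate(ClassifierConfig("lda"), tuple(f"f{i}" for i in range(n_feat)),
                              "SB", rep)

    def test_balance_filter_orders_candidates(self):
        a = self._candidate(0.90, {"high": 0.88, "low": 0.92}, 6)
        b = self._candidate(0.91, {"high": 0.99, "low": 0.60}, 6)
        ranked = select_models([b, a])
        assert ranked[0] is a

    def test_fewer_features_wins_ties(self):
        a = self._candidate(0.90, {"high": 0.9, "low": 0.9}, 6)
        b = self._candidate(0.90, {"high": 0.9, "low": 0.9}, 3)
        assert select_models([a, b])[0] is b

    def test_empty_input(self):
        assert select_models([]) == []
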