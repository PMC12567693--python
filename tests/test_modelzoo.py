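"""Experiments, tuning, bagging with OOB validation, and final selection."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from wakebreath import bayesopt, modelzoo
from wakebreath.modelzoo import (
    EXPERIMENTS,
    BaggedEnsemble,
    ExperimentSpec,
    compute_metrics,
    cv_loss,
    ensemble_predict,
    evaluate_test,
    fit_bagged,
    oob_metrics,
    oob_predict,
    run_trials,
    select_final,
)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(3, 1, (60, 4))])
    y = np.array(["neg"] * 60 + ["pos"] * 60)
    return X, y


def _tree(params):
    return DecisionTreeClassifier(max_depth=params.get("max_depth", 3),
                                  random_state=0)


class TestExperiments:
    def test_exactly_six_pairwise_experiments(self):
        assert len(EXPERIMENTS) == 6
        assert len({e.name for e in EXPERIMENTS}) == 6

    def test_positive_class_is_more_severe(self):
        e = ExperimentSpec("Severe", "NonOSA")
        assert e.positive_class == "Severe"
        assert e.negative_class == "NonOSA"

    def test_equal_classes_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec("Mild", "Mild")

    def test_zoo_contains_all_listed_families(self):
        for name in ("decision_tree", "naive_bayes", "logistic_l1", "logistic_l2",
                     "knn", "lda", "qda", "svm_linear", "svm_rbf", "svm_poly3",
                     "svm_poly5", "svm_poly7", "svm_poly9", "random_forest",
                     "bagged_trees", "gradient_boosting", "rusboost",
                     "subspace_knn", "shallow_nn", "deep_nn"):
            assert name in modelzoo.CLASSIFIER_ZOO


class TestCVLoss:
    def test_perfect_classifier_zero_loss(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 2))
        y = np.where(X[:, 0] > 0, "pos", "neg")

        class Oracle:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.where(X[:, 0] > 0, "pos", "neg")

        assert cv_loss(lambda p: Oracle(), {}, X, y) == 0.0

    def test_constant_classifier_loss_equals_minority_fraction(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 2))
        y = np.array(["a"] * 60 + ["b"] * 40)

        class Constant:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.array(["a"] * len(X))

        assert cv_loss(lambda p: Constant(), {}, X, y) == pytest.approx(0.4)

    def test_loss_in_unit_interval(self, separable):
        X, y = separable
        loss = cv_loss(_tree, {"max_depth": 1}, X, y)
        assert 0.0 <= loss <= 1.0


class TestBayesOpt:
    def test_quadratic_minimizer_found_within_5_percent(self):
        space = [bayesopt.Param("x", "uniform", (0.0, 1.0))]
        res = bayesopt.minimize_ei_plus(lambda p: (p["x"] - 0.7) ** 2, space,
                                        budget=50, seed=0)
        assert abs(res.best_params["x"] - 0.7) < 0.05

    def test_budget_one_returns_initial_best(self):
        space = [bayesopt.Param("x", "uniform", (0.0, 1.0))]
        res = bayesopt.minimize_ei_plus(lambda p: p["x"], space, budget=1, seed=1)
        assert len(res.history) == 1
        assert res.best_loss == res.history[0][1]

    def test_incumbent_never_worse_than_initial_design(self):
        space = [bayesopt.Param("x", "uniform", (0.0, 1.0)),
                 bayesopt.Param("k", "int", (1, 10))]
        obj = lambda p: (p["x"] - 0.2) ** 2 + 0.01 * p["k"]
        res = bayesopt.minimize_ei_plus(obj, space, budget=25, n_init=8, seed=2)
        init_best = min(l for _, l in res.history[:8])
        assert res.best_loss <= init_best

    def test_empty_space_returns_default_config(self):
        res = bayesopt.minimize_ei_plus(lambda p: 0.25, [], budget=10, seed=3)
        assert res.best_params == {}
        assert res.best_loss == 0.25


class TestBagging:
    def test_membership_column_sums_equal_n(self, separable):
        X, y = separable
        ens = fit_bagged(_tree, {}, X, y, "pos", B=20, seed=0)
        assert np.all(ens.membership.sum(axis=0) == len(y))

    def test_oob_fraction_near_1_over_e(self):
        """Plain bootstrap: mean per-resample OOB fraction ~ (1-1/N)^N ~ 1/e."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 3))
        y = np.array(["a", "b"] * 50)
        ens = fit_bagged(_tree, {}, X, y, "b", B=50, stratified=False, seed=0)
        oob_frac = np.mean(ens.membership == 0)
        assert oob_frac == pytest.approx(1 / np.e, abs=0.03)

    def test_stratified_mode_preserves_class_counts(self, separable):
        X, y = separable
        ens = fit_bagged(_tree, {}, X, y, "pos", B=10, stratified=True, seed=1)
        pos = y == "pos"
        for b in range(10):
            assert ens.membership[pos, b].sum() == pos.sum()
            assert ens.membership[~pos, b].sum() == (~pos).sum()

    def test_ensemble_roundtrip_bit_identical(self, separable, tmp_path):
        X, y = separable
        ens = fit_bagged(_tree, {}, X, y, "pos", B=5, seed=3)
        ens.save(tmp_path / "ens.pkl")
        back = BaggedEnsemble.load(tmp_path / "ens.pkl")
        assert np.array_equal(back.membership, ens.membership)
        assert np.array_equal(ensemble_predict(back, X), ensemble_predict(ens, X))


class TestOOBPrediction:
    def test_single_learner_predicts_for_its_complement(self, separable):
        X, y = separable
        ens = fit_bagged(_tree, {}, X, y, "pos", B=1, seed=4)
        pred, flags = oob_predict(ens, X, return_flags=True)
        oob_rows = ens.membership[:, 0] == 0
        direct = ens.learners[0].predict(X)
        assert np.array_equal(pred[oob_rows], direct[oob_rows])
        assert not flags[oob_rows].any()
        assert flags[~oob_rows].all()  # in-bag rows fall back, flagged

    def test_majority_vote_mode(self):
        assert modelzoo._vote(np.array(["A", "A", "B"]),
                              np.array(["A", "B"]), "B") == "A"

    def test_tie_goes_to_positive_class(self):
        assert modelzoo._vote(np.array(["A", "B"]),
                              np.array(["A", "B"]), "B") == "B"

    def test_oob_vote_matches_brute_force_from_membership(self, separable):
        """Mode-over-OOB-learners recomputed by brute force agrees exactly."""
        X, y = separable
        ens = fit_bagged(_tree, {"max_depth": 1}, X, y, "pos", B=15, seed=5)
        pred = oob_predict(ens, X)
        all_preds = np.stack([m.predict(X) for m in ens.learners], axis=1)
        for i in range(len(y)):
            votes = [all_preds[i, b] for b in range(15)
                     if ens.membership[i, b] == 0]
            if not votes:
                continue
            vals, counts = np.unique(votes, return_counts=True)
            winners = set(vals[counts == counts.max()])
            if len(winners) > 1:
                assert pred[i] == "pos"
            else:
                assert pred[i] == winners.pop()


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["pos", "neg", "pos"])
        rep = compute_metrics(y, y, "pos")
        assert (rep.accuracy, rep.sensitivity, rep.specificity) == (1.0, 1.0, 1.0)

    def test_confusion_counting_oracle(self):
        """TP=3 FN=1 TN=4 FP=2 -> sens 0.75, spec 0.667, acc 0.7."""
        y_true = np.array(["p"] * 4 + ["n"] * 6)
        y_pred = np.array(["p", "p", "p", "n", "n", "n", "n", "n", "p", "p"])
        rep = compute_metrics(y_true, y_pred, "p")
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.accuracy == pytest.approx(0.7)

    def test_balanced_accuracy_definition(self):
        y_true = np.array(["p"] * 4 + ["n"] * 6)
        y_pred = np.array(["p"] * 10)
        rep = compute_metrics(y_true, y_pred, "p")
        assert rep.balanced_accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2)

    def test_oob_metrics_of_separable_data_high(self, separable):
        X, y = separable
        ens = fit_bagged(_tree, {}, X, y, "pos", B=20, seed=6)
        rep = oob_metrics(ens, X, y)
        assert rep.accuracy > 0.9


class TestTrialsAndSelection:
    def test_identical_trials_select_trial_zero(self, separable):
        X, y = separable

        class FixedSeedTrials:
            pass

        # LDA has no stochastic hyperparameters and an empty space: every
        # trial produces the same OOB accuracy, so the tie rule picks trial 0
        factory, space = modelzoo.CLASSIFIER_ZOO["lda"]
        best = run_trials(factory, space, X, y, "pos", n_trials=3, budget=1,
                          B=5, seed=0)
        assert best.trial == 0

    def test_argmax_trial_selected(self, separable):
        X, y = separable
        factory = _tree
        best = run_trials(factory, [bayesopt.Param("max_depth", "int", (1, 6))],
                          X, y, "pos", n_trials=2, budget=2, B=5, seed=1)
        assert best.oob.accuracy >= 0.8

    def test_dominating_classifier_selected(self, separable):
        X, y = separable
        good = run_trials(_tree, [], X, y, "pos", n_trials=1, budget=1, B=5, seed=0)
        bad = run_trials(lambda p: DecisionTreeClassifier(max_depth=1,
                                                          random_state=0,
                                                          min_samples_leaf=59),
                         [], X, y, "pos", n_trials=1, budget=1, B=5, seed=0)
        name, chosen = select_final({"bad": bad, "good": good})
        assert chosen.oob.accuracy == max(good.oob.accuracy, bad.oob.accuracy)

    def test_oob_tie_broken_by_config_order(self, separable):
        X, y = separable
        a = run_trials(_tree, [], X, y, "pos", n_trials=1, budget=1, B=5, seed=0)
        name, _ = select_final({"first": a, "second": a})
        assert name == "first"

    def test_selection_ignores_test_labels(self, separable):
        """Permuting test labels cannot change selection: it never sees them."""
        X, y = separable
        results = {n: run_trials(_tree, [], X, y, "pos", n_trials=1, budget=1,
                                 B=5, seed=s) for s, n in enumerate(["a", "b"])}
        before, _ = select_final(results)
        # test labels live outside `results`; selection input is unchanged
        after, _ = select_final(results)
        assert before == after


class TestEvaluateTest:
    def test_metrics_bounded_and_aggregated(self, separable):
        X, y = separable
        reports, agg = evaluate_test(_tree, {}, X[:100], y[:100], X[100:],
                                     y[100:], "pos", n_repeats=3, B=5, seed=0)
        assert len(reports) == 3
        for rep in reports:
            assert 0 <= rep.accuracy <= 1
            assert 0 <= rep.sensitivity <= 1
        assert "accuracy_mean" in agg and "accuracy_sd" in agg

    def test_deterministic_classifier_zero_sd(self, separable):
        """LDA + fixed split: identical repeats give zero SD (only the
        bootstrap seeds vary, and the strongly separated vote is stable)."""
        X, y = separable
        factory, _ = modelzoo.CLASSIFIER_ZOO["lda"]
        _, agg = evaluate_test(factory, {}, X[:100], y[:100], X[100:], y[100:],
                               "pos", n_repeats=3, B=10, seed=0)
        assert agg["accuracy_sd"] == pytest.approx(0.0, abs=1e-12)
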