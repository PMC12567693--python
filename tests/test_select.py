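"""Normalization choice, three-stage selection, Shapley ranking, fusion."""

import numpy as np
import pandas as pd
import pytest

from wakebreath import select, shapley, synthgen


@pytest.fixture(scope="module")
def binary_data():
    rng = np.random.default_rng(0)
    n = 300
    X = pd.DataFrame({
        "informative": np.concatenate([rng.normal(0, 1, n // 2),
                                       rng.normal(2, 1, n // 2)]),
        "noise": rng.standard_normal(n),
        "constant": np.ones(n),
    })
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestMutualInformation:
    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 10_000)
        x = rng.standard_normal(10_000)
        assert select.mutual_information_bits(x, y) < 0.01

    def test_perfectly_separating_feature_near_one_bit(self):
        rng = np.random.default_rng(2)
        y = rng.permutation(np.repeat([0, 1], 5_000))  # exactly balanced
        x = y + 0.01 * rng.standard_normal(10_000)
        assert select.mutual_information_bits(x, y) == pytest.approx(1.0, abs=0.02)

    def test_constant_feature_zero_without_error(self):
        y = np.array([0, 1] * 50)
        assert select.mutual_information_bits(np.ones(100), y) == 0.0


class TestNormalization:
    def test_choice_is_from_candidate_list(self, binary_data):
        X, y = binary_data
        choice = select.choose_normalization(X, y)
        assert choice.method in select.NORMALIZATION_CANDIDATES

    def test_zscore_canonical_moments_on_training(self, binary_data):
        X, _ = binary_data
        norm = select.fit_normalizer(X, "zscore")
        Xn = norm.transform(X)
        assert abs(Xn["informative"].mean()) < 1e-9
        assert Xn["informative"].std(ddof=0) == pytest.approx(1.0)

    def test_minmax_canonical_range(self, binary_data):
        X, _ = binary_data
        Xn = select.fit_normalizer(X, "minmax").transform(X)
        assert Xn["noise"].min() == pytest.approx(0.0)
        assert Xn["noise"].max() == pytest.approx(1.0)

    def test_rank_maps_training_into_unit_interval(self, binary_data):
        X, _ = binary_data
        Xn = select.fit_normalizer(X, "rank").transform(X)
        assert (Xn["noise"] >= 0).all() and (Xn["noise"] <= 1).all()

    def test_parameters_frozen_at_fit(self, binary_data):
        """Transforming new data reuses the training parameters."""
        X, _ = binary_data
        norm = select.fit_normalizer(X, "zscore")
        fresh = X + 100.0
        Xn = norm.transform(fresh)
        expected = (fresh - norm.params["mean"]) / norm.params["sd"]
        pd.testing.assert_frame_equal(Xn, expected)
        assert Xn["noise"].mean() > 50.0  # training parameters, not refit


class TestTTestFilter:
    def test_equal_distributions_dropped(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"same": rng.standard_normal(2000)})
        y = np.array([0, 1] * 1000)
        assert select.ttest_filter(X, y, alpha=0.05) == []

    def test_hand_welch_statistic(self):
        """Groups {1,2,3} vs {2,3,4}: t = -1/sqrt(2/3) = -1.2247."""
        from scipy import stats

        t, _ = stats.ttest_ind([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], equal_var=False)
        assert t == pytest.approx(-1.0 / np.sqrt(2.0 / 3.0))

    def test_survivors_subset_of_input(self, binary_data):
        X, y = binary_data
        surv = select.ttest_filter(X, y)
        assert set(surv) <= set(X.columns)
        assert "informative" in surv


class TestShapleyRanking:
    def test_linear_model_matches_closed_form_and_brute_force(self):
        """w_i (x_i - E[x_i]) for independent features, verified against the
        enumeration of all 2^3 coalitions."""
        rng = np.random.default_rng(4)
        w = np.array([2.0, -1.0, 0.5])
        predict = lambda M: M @ w
        X = rng.standard_normal((5, 3))
        bg = rng.standard_normal((100, 3))
        phi = shapley.shapley_values(predict, X, bg)
        assert np.allclose(phi, w * (X - bg.mean(axis=0)), atol=1e-10)
        # brute force over all coalitions with interventional values
        from itertools import combinations
        from math import factorial

        def brute(x):
            d = 3
            out = np.zeros(d)
            for i in range(d):
                rest = [j for j in range(d) if j != i]
                for k in range(d):
                    for S in combinations(rest, k):
                        weight = factorial(k) * factorial(d - k - 1) / factorial(d)
                        z_with = bg.copy()
                        z_without = bg.copy()
                        for j in S:
                            z_with[:, j] = x[j]
                            z_without[:, j] = x[j]
                        z_with[:, i] = x[i]
                        out[i] += weight * (predict(z_with).mean()
                                            - predict(z_without).mean())
            return out

        assert np.allclose(phi[0], brute(X[0]), atol=1e-10)

    def test_local_accuracy_exact(self):
        rng = np.random.default_rng(5)
        predict = lambda M: np.sin(M).sum(axis=1) + (M[:, 0] * M[:, 1])
        X = rng.standard_normal((4, 8))
        bg = rng.standard_normal((30, 8))
        phi = shapley.shapley_values(predict, X, bg, n_permutations=2, rng=rng)
        assert np.allclose(phi.sum(axis=1),
                           predict(X) - predict(bg).mean(), atol=1e-9)

    def test_single_feature_model_attributes_only_that_feature(self):
        rng = np.random.default_rng(6)
        predict = lambda M: 3.0 * M[:, 2]
        X = rng.standard_normal((5, 4))
        bg = rng.standard_normal((40, 4))
        phi = shapley.shapley_values(predict, X, bg)
        assert np.allclose(phi[:, [0, 1, 3]], 0.0, atol=1e-12)
        assert np.all(np.abs(phi[:, 2]) > 0)

    def test_rank_is_permutation_and_finds_signal(self, binary_data):
        X, y = binary_data
        ranked = select.shap_rank(X, y, seed=0)
        assert sorted(ranked) == sorted(X.columns)
        assert ranked[0] == "informative"


class TestRFE:
    def test_target_equal_to_size_is_identity(self, binary_data):
        X, y = binary_data
        assert select.rfe_rusboost(X, y, target_k=3) == list(X.columns)

    def test_output_size_exact(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((120, 12)),
                         columns=[f"f{i}" for i in range(12)])
        y = (X["f0"] + 0.3 * rng.standard_normal(120) > 0).astype(int).to_numpy()
        surv = select.rfe_rusboost(X, y, target_k=4, seed=0)
        assert len(surv) == 4

    def test_planted_informative_features_recovered(self):
        rng = np.random.default_rng(8)
        n = 400
        X = pd.DataFrame(rng.standard_normal((n, 30)),
                         columns=[f"f{i}" for i in range(30)])
        y = (X[[f"f{i}" for i in range(5)]].sum(axis=1)
             + 0.8 * rng.standard_normal(n) > 0).astype(int).to_numpy()
        surv = select.rfe_rusboost(X, y, target_k=10, seed=0)
        assert len(set(surv) & {f"f{i}" for i in range(5)}) >= 4


class TestRUSBoost:
    def test_learns_imbalanced_separation(self):
        rng = np.random.default_rng(9)
        n_maj, n_min = 300, 40
        X = np.vstack([rng.normal(0, 1, (n_maj, 4)),
                       rng.normal(1.5, 1, (n_min, 4))])
        y = np.array([0] * n_maj + [1] * n_min)
        model = select.RUSBoostClassifier(n_estimators=60, random_state=0).fit(X, y)
        pred = model.predict(X)
        sens = np.mean(pred[y == 1] == 1)
        assert sens > 0.6  # undersampling keeps minority detection up

    def test_importances_normalized(self, binary_data):
        X, y = binary_data
        m = select.RUSBoostClassifier(n_estimators=20, random_state=0)
        m.fit(X.to_numpy(), y)
        assert m.feature_importances_.sum() == pytest.approx(1.0, abs=1e-6)


class TestFusion:
    @pytest.fixture
    def records(self):
        spec = synthgen.CohortSpec(n_per_class={"NonOSA": 5, "Severe": 5}, seed=1)
        return synthgen.generate_cohort(spec)

    def test_34_acoustic_plus_block_is_41(self, records):
        rng = np.random.default_rng(0)
        acoustic = pd.DataFrame(rng.standard_normal((10, 34)),
                                columns=[f"a{i}" for i in range(34)],
                                index=[r.subject_id for r in records])
        fused = select.fuse_with_anthropometrics(acoustic, records)
        assert len(fused.feature_names) == 41

    def test_no_acoustic_gives_block_only(self, records):
        empty = pd.DataFrame(index=[r.subject_id for r in records])
        fused = select.fuse_with_anthropometrics(empty, records)
        assert len(fused.feature_names) == 7

    def test_column_order_acoustic_then_anthropometric(self, records):
        acoustic = pd.DataFrame(np.zeros((10, 2)), columns=["a0", "a1"],
                                index=[r.subject_id for r in records])
        fused = select.fuse_with_anthropometrics(acoustic, records)
        assert fused.feature_names[:2] == ["a0", "a1"]
        assert fused.feature_names[2:] == ["bmi", "age", "sex", "smoke",
                                           "nc", "mps", "sex_x_bmi"]
        assert len(set(fused.feature_names)) == len(fused.feature_names)


class TestStageNesting:
    def test_full_selection_stages_are_nested(self, binary_data):
        X, y = binary_data
        rng = np.random.default_rng(10)
        X = X.copy()
        for i in range(8):
            X[f"extra{i}"] = rng.standard_normal(len(X))
        spec = synthgen.CohortSpec(n_per_class={"NonOSA": 150, "Severe": 150},
                                   seed=2)
        records = synthgen.generate_cohort(spec)[: len(X)]
        X.index = [r.subject_id for r in records]
        res = select.select_features(X, y, records, n_acoustic=3, seed=0)
        assert set(res.wrapper_survivors) <= set(res.embedded_ranking)
        assert set(res.embedded_ranking) <= set(res.filter_survivors) | set(X.columns)
        assert len(res.fused.feature_names) == 3 + 7
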