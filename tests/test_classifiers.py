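"""Classifier contracts: least-squares solutions against a pseudo-inverse
oracle, quadratic expansion geometry, the centroid-displacement rule, and
subject-wise hyperparameter selection."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from physioact.classifiers import (CDNN, LeastSquaresClassifier,
                                   MajorityClassifier, make_classifier,
                                   one_hot, quadratic_expand, rf_max_features,
                                   select_hyperparameters)


class TestLslc:
    def test_weights_match_pseudoinverse_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        y = rng.integers(0, 3, 50)
        model = LeastSquaresClassifier().fit(X, y)
        Xa = np.hstack([X, np.ones((50, 1))])
        W_oracle = np.linalg.pinv(Xa) @ one_hot(y, np.unique(y))
        assert np.max(np.abs(model.W_ - W_oracle)) < 1e-8

    def test_separable_clouds_zero_training_error(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (30, 2)),
                       rng.normal(5, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = LeastSquaresClassifier().fit(X, y)
        assert np.mean(model.predict(X) != y) == 0.0

    def test_discriminants_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 4))
        y = rng.integers(0, 4, 80)
        model = LeastSquaresClassifier().fit(X, y)
        sums = model.decision_function(rng.normal(size=(20, 4))).sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-8

    def test_design_mse_reported(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        model = LeastSquaresClassifier().fit(X, y)
        Y = one_hot(y, model.classes_)
        pred = model.decision_function(X)
        assert model.design_mse_ == pytest.approx(np.mean((pred - Y) ** 2))


class TestLsqc:
    def test_expansion_column_count(self):
        X = np.zeros((5, 3))
        # 3 linear + 3 squares + 3 cross terms; the solver adds the intercept
        assert quadratic_expand(X).shape[1] == 9

    def test_circle_separation(self):
        rng = np.random.default_rng(4)
        r = np.concatenate([rng.uniform(0, 0.8, 100), rng.uniform(1.5, 2.5, 100)])
        th = rng.uniform(0, 2 * np.pi, 200)
        X = np.column_stack([r * np.cos(th), r * np.sin(th)])
        y = np.array([0] * 100 + [1] * 100)
        lsqc_err = np.mean(LeastSquaresClassifier(quadratic=True)
                           .fit(X, y).predict(X) != y)
        lslc_err = np.mean(LeastSquaresClassifier().fit(X, y).predict(X) != y)
        assert lsqc_err == 0.0
        assert lslc_err > 0.25

    def test_nested_model_on_linear_data(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-2, 1, (50, 2)), rng.normal(2, 1, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        err_l = np.mean(LeastSquaresClassifier().fit(X, y).predict(X) != y)
        err_q = np.mean(LeastSquaresClassifier(quadratic=True)
                        .fit(X, y).predict(X) != y)
        assert err_q <= err_l


class TestCdnn:
    def test_k1_is_nearest_neighbour(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0]])
        y = np.array(["a", "b"])
        model = CDNN(k=1).fit(X, y)
        assert model.predict([[1.0, 0.0]])[0] == "a"
        assert model.predict([[9.0, 0.0]])[0] == "b"

    def test_homogeneous_neighbourhood(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        y = np.array([0] * 5 + [1] * 5)
        assert CDNN(k=3).fit(X, y).predict([[0.1, 0.0]])[0] == 0

    def test_disagrees_with_majority_vote(self):
        # 2 class-A neighbours centred at the origin, 1 class-B neighbour
        # right next to the query: displacement favours B, majority says A.
        X = np.array([[0.0, 1.0], [0.0, -1.0], [0.6, 0.0],
                      [50.0, 50.0], [-50.0, 50.0]])
        y = np.array(["A", "A", "B", "A", "B"])
        x = np.array([[0.5, 0.0]])
        cdnn = CDNN(k=3).fit(X, y)
        # verify the displacement rule by direct computation
        disp_a = np.linalg.norm(x[0] - np.array([0.0, 0.0])) / 3
        disp_b = np.linalg.norm(x[0] - np.array([0.6, 0.0])) / 2
        assert disp_b < disp_a
        assert cdnn.predict(x)[0] == "B"
        from sklearn.neighbors import KNeighborsClassifier
        knn = KNeighborsClassifier(n_neighbors=3).fit(X, y)
        assert knn.predict(x)[0] == "A"

    def test_k_larger_than_design_rejected(self):
        with pytest.raises(ValueError):
            CDNN(k=5).fit(np.zeros((3, 2)), np.array([0, 1, 0]))


class TestGenericLearners:
    def test_rf_feature_subsampling_formula(self):
        assert rf_max_features(40) == 6
        assert rf_max_features(1) == 1
        assert rf_max_features(533) == 10

    @pytest.mark.parametrize("kind", ["lslc", "lsqc", "knn", "cdnn",
                                      "linsvm", "rbfsvm", "mlp8", "rf"])
    def test_all_learners_fit_separated_blobs(self, kind):
        centers = [(0, 0), (8, 0), (0, 8), (8, 8)]  # square layout avoids
        X, y = make_blobs(n_samples=160, centers=centers,  # LS masking
                          cluster_std=0.4, random_state=0)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)  # pipeline contract
        hp = {"gamma": 0.5} if kind == "rbfsvm" else {}
        model = make_classifier(kind, seed=0, **hp)
        model.fit(Z, y)
        assert np.mean(model.predict(Z) != y) < 0.05

    def test_mlp_early_stopping_configured(self):
        model = make_classifier("mlp12", seed=1)
        assert model.early_stopping and model.validation_fraction == 0.2
        assert model.hidden_layer_sizes == (12,)
        X, y = make_blobs(n_samples=120, centers=2, random_state=1)
        model.fit(X, y)
        # a validation curve was monitored and training stopped finitely
        assert len(model.validation_scores_) == model.n_iter_
        assert model.n_iter_ <= model.max_iter

    def test_stochastic_learners_deterministic_with_seed(self):
        X, y = make_blobs(n_samples=100, centers=3, random_state=2)
        p1 = make_classifier("rf", seed=7).fit(X, y).predict(X)
        p2 = make_classifier("rf", seed=7).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_majority_baseline(self):
        X = np.zeros((8, 2))
        y = np.array([0, 0, 0, 1, 1, 2, 2, 3])
        model = MajorityClassifier().fit(X, y)
        assert np.all(model.predict(X) == 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("perceptron")


class TestHyperparameterSelection:
    def _noisy_threshold_data(self, seed=0, n=240):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 1))
        y = (X[:, 0] > 0).astype(int)
        flip = rng.random(n) < 0.25
        y[flip] = 1 - y[flip]
        groups = np.repeat(np.arange(6), n // 6)
        return X, y, groups

    def test_degenerate_grid(self):
        X, y, g = self._noisy_threshold_data()
        assert select_hyperparameters("knn", X, y, g, [{"k": 3}]) == {"k": 3}

    def test_empty_grid_rejected(self):
        X, y, g = self._noisy_threshold_data()
        with pytest.raises(ValueError):
            select_hyperparameters("knn", X, y, g, [])

    def test_label_noise_selects_k_above_one(self):
        X, y, g = self._noisy_threshold_data(seed=3)
        grid = [{"k": k} for k in range(1, 26, 2)]
        best = select_hyperparameters("knn", X, y, g, grid)
        assert best["k"] > 1

    def test_validation_rows_never_seen_at_fit_time(self):
        X, y, g = self._noisy_threshold_data()
        X = np.column_stack([X, np.arange(len(X))])  # row id channel
        seen = []

        class Recorder:
            def __init__(self, **kw):
                pass

            def fit(self, Xd, yd):
                seen.append(set(Xd[:, 1].astype(int)))
                return self

            def predict(self, Xv):
                return np.zeros(len(Xv), dtype=int)

        def factory(seed=None, **params):
            return Recorder(**params)

        select_hyperparameters(factory, X, y, g, [{"a": 1}, {"a": 2}])
        fold_ids = [set(np.flatnonzero(g == gg)) for gg in np.unique(g)]
        # each fit excluded exactly one fold, and that fold was never seen
        for s in seen:
            excluded = [f for f in fold_ids if not (s & f)]
            assert len(excluded) == 1
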