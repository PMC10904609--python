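"""Discriminant analysis, softmax regression, ensembles, and grid search."""

import numpy as np
import pytest

from hemonet.containers import FINGERS
from hemonet.models import (
    LDA_GRID,
    MNLR_GRID,
    QDA_GRID,
    RF_GRID,
    XGB_GRID,
    LinearDiscriminantClassifier,
    MultinomialLogisticRegression,
    QuadraticDiscriminantClassifier,
    RandomForestFingerClassifier,
    XGBoostFingerClassifier,
    grid_search_cv,
    make_model,
    scatter_matrices,
)


class TestScatterMatrices:
    def test_hand_computed_three_class_2d(self):
        """S_W and S_B verified by hand arithmetic on a 6-point toy set."""
        X = np.array([[0.0, 0], [2, 0], [4, 0], [6, 0], [1, 2], [3, 2]])
        y = np.array(["a", "a", "b", "b", "c", "c"])
        S_W, S_B, evals, evecs = scatter_matrices(X, y)
        # class means: a=(1,0), b=(5,0), c=(2,2); overall mean=(8/3, 2/3)
        # within: each class contributes [[2,0],[0,0]] -> total [[6,0],[0,0]]
        assert np.allclose(S_W, [[6.0, 0.0], [0.0, 0.0]])
        mu = X.mean(axis=0)
        S_B_hand = sum(
            2 * np.outer(m - mu, m - mu)
            for m in ([1.0, 0.0], [5.0, 0.0], [2.0, 2.0])
        )
        assert np.allclose(S_B, S_B_hand)

    def test_identical_class_means_zero_between_scatter(self):
        X = np.array([[1.0, 0], [-1, 0], [1, 1], [-1, 1]])
        y = np.array(["a", "a", "b", "b"])
        X[2:] -= X[2:].mean(axis=0) - X[:2].mean(axis=0)
        S_W, S_B, evals, _ = scatter_matrices(X, y)
        assert np.allclose(S_B, 0.0, atol=1e-12)
        assert np.allclose(evals, 0.0, atol=1e-12)


class TestDiscriminantClassifiers:
    def test_lda_separable_two_gaussians(self, rng):
        X = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])[:, None]
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = LinearDiscriminantClassifier().fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0
        assert model.within_scatter_.shape == (1, 1)

    def test_qda_posterior_normalisation_and_dominance(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = QuadraticDiscriminantClassifier(reg_param=0.1).fit(X, y)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(proba >= 0)
        # a point at a class mean, far from others -> dominant posterior
        k = model.classes_.tolist().index("thumb")
        p = model.predict_proba(model.means_[k][None, :])
        assert p[0, k] > 0.99

    def test_qda_equal_covariance_limit_agrees_with_lda(self, rng):
        """With shared covariance the QDA boundary is linear; decisions agree
        with LDA on nearly every sample."""
        n = 400
        X = np.concatenate([rng.normal(-1.0, 1.0, n), rng.normal(1.0, 1.0, n)])[:, None]
        y = np.array(["a"] * n + ["b"] * n)
        lda = LinearDiscriminantClassifier().fit(X, y)
        qda = QuadraticDiscriminantClassifier(reg_param=1.0).fit(X, y)
        agree = (lda.predict(X) == qda.predict(X)).mean()
        assert agree >= 0.95


class TestMNLR:
    def test_zero_weights_uniform_probabilities(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = MultinomialLogisticRegression().fit(X[:50], y[:50])
        model.coef_ = np.zeros_like(model.coef_)
        model.intercept_ = np.zeros_like(model.intercept_)
        proba = model.predict_proba(X[:10])
        assert np.allclose(proba, 1.0 / len(model.classes_), atol=1e-12)

    def test_reference_class_parameterisation_shape(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = MultinomialLogisticRegression().fit(X, y)
        # K-1 weight vectors; the last class is the reference
        assert model.coef_.shape == (4, X.shape[1])

    def test_separable_two_class_perfect_training_accuracy(self, rng):
        X = np.concatenate([rng.normal(-4, 0.5, 60), rng.normal(4, 0.5, 60)])[:, None]
        y = np.array(["a"] * 60 + ["b"] * 60)
        model = MultinomialLogisticRegression(C=20).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_gradient_norm_small_at_optimum(self, gaussian_blobs):
        """The penalised-loss gradient at the returned optimum is ~0,
        checked with an independent numerical gradient."""
        X, y = gaussian_blobs
        X = X[:100]
        yy = y[:100]
        model = MultinomialLogisticRegression(penalty="l2", C=1.0, tol=1e-6)
        model.fit(X, yy)
        W = np.hstack([model.coef_, model.intercept_[:, None]])
        Xd = np.hstack([X, np.ones((X.shape[0], 1))])
        enc = {c: i for i, c in enumerate(model.classes_)}
        Y = np.array([enc[c] for c in yy])

        def loss(Wf):
            Wm = Wf.reshape(W.shape)
            z = Xd @ Wm.T
            zf = np.hstack([z, np.zeros((z.shape[0], 1))])
            zf -= zf.max(axis=1, keepdims=True)
            logp = zf - np.log(np.exp(zf).sum(axis=1, keepdims=True))
            nll = -logp[np.arange(len(Y)), Y].sum()
            return nll + np.sum(Wm[:, :-1] ** 2) / 2.0

        g = np.zeros(W.size)
        eps = 1e-6
        Wf = W.ravel().copy()
        for i in range(W.size):
            Wf[i] += eps
            fp = loss(Wf)
            Wf[i] -= 2 * eps
            fm = loss(Wf)
            Wf[i] += eps
            g[i] = (fp - fm) / (2 * eps)
        assert np.linalg.norm(g) < 1e-3 * max(1.0, np.linalg.norm(W))

    def test_l1_drives_weights_sparse(self, gaussian_blobs):
        X, y = gaussian_blobs
        strong = MultinomialLogisticRegression(penalty="l1", C=0.01).fit(X, y)
        weak = MultinomialLogisticRegression(penalty="l1", C=10).fit(X, y)
        assert np.sum(np.abs(strong.coef_) < 1e-8) > np.sum(np.abs(weak.coef_) < 1e-8)

    def test_agrees_with_sklearn_predictions(self, gaussian_blobs):
        """Cross-check against the symmetric-softmax solver on separable
        data, where both parameterisations recover the same classes."""
        from sklearn.linear_model import LogisticRegression

        X, y = gaussian_blobs
        ours = MultinomialLogisticRegression(penalty="l2", C=1.0).fit(X, y)
        theirs = LogisticRegression(C=1.0, max_iter=2000).fit(X, y)
        assert (ours.predict(X) == theirs.predict(X)).mean() > 0.98


class TestEnsembles:
    def test_grids_match_protocol_constants(self):
        assert RF_GRID == {
            "n_estimators": [50, 100], "max_depth": [None, 5, 10],
            "min_samples_split": [2, 5], "min_samples_leaf": [1, 4],
        }
        assert XGB_GRID == {
            "n_estimators": [50, 100], "max_depth": [None, 5, 10],
            "learning_rate": [0.1, 0.01, 0.001],
        }
        assert QDA_GRID == {"reg_param": [0.0, 0.1, 0.5, 1.0]}
        assert MNLR_GRID == {"penalty": ["l1", "l2"], "C": [0.01, 0.1, 1, 10, 20]}
        lda_cells = [(s, sh) for g in LDA_GRID
                     for s in g["solver"] for sh in g["shrinkage"]]
        assert set(lda_cells) == {
            ("svd", None), ("lsqr", None), ("lsqr", "auto"),
            ("eigen", None), ("eigen", "auto"),
        }

    def test_rf_solves_xor(self, rng):
        n = 400
        X = rng.uniform(-1, 1, size=(n, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, "a", "b")
        tr, te = slice(0, 300), slice(300, None)
        model = RandomForestFingerClassifier(random_state=0).fit(X[tr], y[tr])
        assert (model.predict(X[te]) == y[te]).mean() > 0.9

    def test_rf_feature_importances_exposed(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = RandomForestFingerClassifier(n_estimators=50, random_state=0).fit(X, y)
        imp = model.feature_importances_
        assert imp.shape == (X.shape[1],)
        assert imp.sum() == pytest.approx(1.0)

    def test_boosting_training_loss_decreases(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = XGBoostFingerClassifier(n_estimators=40, max_depth=5, random_state=0)
        curve = model.train_loss_curve(X, y)
        assert curve[-1] < curve[0]
        # monotone within tolerance of floating noise
        assert np.all(np.diff(curve) <= 1e-9)

    def test_xgb_none_depth_accepted(self, gaussian_blobs):
        X, y = gaussian_blobs
        model = XGBoostFingerClassifier(
            n_estimators=20, max_depth=None, random_state=0
        ).fit(X, y)
        assert (model.predict(X) == y).mean() > 0.95


class TestGridSearch:
    def test_single_cell_grid_returned(self, gaussian_blobs):
        X, y = gaussian_blobs
        best, params, table = grid_search_cv(
            QuadraticDiscriminantClassifier(), {"reg_param": [0.5]}, X, y
        )
        assert params == {"reg_param": 0.5}
        assert len(table) == 1

    def test_tie_broken_first_in_grid(self, gaussian_blobs):
        """Duplicate cells necessarily tie; the first wins."""
        X, y = gaussian_blobs
        best, params, table = grid_search_cv(
            QuadraticDiscriminantClassifier(),
            [{"reg_param": [0.1]}, {"reg_param": [0.1]}],
            X, y,
        )
        assert len(table) == 2
        assert table["mean_test_score"][0] == table["mean_test_score"][1]
        assert params == {"reg_param": 0.1}

    def test_degenerate_versus_adequate_cell(self, rng):
        """On nonlinear (XOR) data, depth-1 trees lose to adequate depth."""
        n = 500
        X = rng.uniform(-1, 1, size=(n, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, "a", "b")
        best, params, _ = grid_search_cv(
            RandomForestFingerClassifier(n_estimators=50, random_state=0),
            {"max_depth": [1, 8]}, X, y,
        )
        assert params == {"max_depth": 8}

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array(["a"] * 9 + ["b"] * 3)
        with pytest.raises(ValueError, match="5-fold"):
            grid_search_cv(QuadraticDiscriminantClassifier(), QDA_GRID, X, y)

    def test_empty_grid_rejected(self, gaussian_blobs):
        X, y = gaussian_blobs
        with pytest.raises(ValueError, match="empty"):
            grid_search_cv(QuadraticDiscriminantClassifier(), {}, X, y)

    def test_lda_grid_search_runs(self, gaussian_blobs):
        X, y = gaussian_blobs
        best, params, table = grid_search_cv(
            LinearDiscriminantClassifier(), LDA_GRID, X, y
        )
        assert len(table) == 5
        assert set(params) == {"solver", "shrinkage"}


class TestRegistry:
    def test_all_ten_models_constructible(self):
        names = ["lda", "qda", "mnlr", "rf", "xgboost",
                 "dnn", "lstm", "bilstm", "hybrid", "hemonet"]
        for name in names:
            assert make_model(name) is not None

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            make_model("svm")

    def test_probabilities_sum_to_one_classical(self, gaussian_blobs):
        X, y = gaussian_blobs
        for name in ("lda", "qda", "mnlr", "rf", "xgboost"):
            model = make_model(name).fit(X, y)
            proba = model.predict_proba(X[:25])
            assert proba.shape == (25, len(FINGERS))
            assert np.all(proba >= -1e-12)
            assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
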