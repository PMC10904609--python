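"""The ten-classifier suite under one scikit-learn fit/predict contract.

Classical models: linear and quadratic discriminant analysis, multinomial
logistic regression (reference-class softmax), random forest, and XGBoost,
each with its cross-validated hyperparameter grid.  Deep models: a dense
baseline, LSTM, bidirectional LSTM, a CNN-LSTM hybrid, and the Hemo-Net
inception network, trained with batch size 32, L2 penalty, and either a
triangular cyclic learning rate (DNN, Hemo-Net) or a fixed 1e-4 rate
(recurrent/hybrid), with early stopping.

All estimators expose ``predict_proba`` returning rows that are
nonnegative and sum to one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_X_y, check_array
import xgboost as xgb

from .nn.architectures import (
    build_baseline_dnn,
    build_bilstm,
    build_hemo_net,
    build_hybrid,
    build_lstm,
)
from .nn.training import TrainingPlan, predict_proba_net, train_deep

__all__ = [
    "LDA_GRID", "QDA_GRID", "MNLR_GRID", "RF_GRID", "XGB_GRID",
    "scatter_matrices",
    "LinearDiscriminantClassifier", "QuadraticDiscriminantClassifier",
    "MultinomialLogisticRegression",
    "RandomForestFingerClassifier", "XGBoostFingerClassifier",
    "DNNClassifier", "LSTMClassifier", "BiLSTMClassifier",
    "HybridClassifier", "HemoNetClassifier",
    "grid_search_cv",
    "fit_lda", "fit_qda", "fit_mnlr", "fit_forest", "fit_boost",
    "MODEL_REGISTRY", "make_model", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# hyperparameter grids (the study's search spaces)
# ---------------------------------------------------------------------------

#: solver x shrinkage; shrinkage is undefined for the svd solver, so that
#: cell is enumerated with shrinkage None only.
LDA_GRID: list[dict] = [
    {"solver": ["svd"], "shrinkage": [None]},
    {"solver": ["lsqr", "eigen"], "shrinkage": [None, "auto"]},
]

QDA_GRID: dict = {"reg_param": [0.0, 0.1, 0.5, 1.0]}

MNLR_GRID: dict = {"penalty": ["l1", "l2"], "C": [0.01, 0.1, 1, 10, 20]}

RF_GRID: dict = {
    "n_estimators": [50, 100],
    "max_depth": [None, 5, 10],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 4],
}

XGB_GRID: dict = {
    "n_estimators": [50, 100],
    "max_depth": [None, 5, 10],
    "learning_rate": [0.1, 0.01, 0.001],
}


# ---------------------------------------------------------------------------
# discriminant analysis
# ---------------------------------------------------------------------------

def scatter_matrices(X: np.ndarray, y: np.ndarray):
    """Within- and between-class scatter matrices and the generalized
    eigenpairs of inv(S_W) @ S_B (descending eigenvalues).

    S_W = sum_k sum_{x in k} (x - mu_k)(x - mu_k)^T
    S_B = sum_k n_k (mu_k - mu)(mu_k - mu)^T

    A singular S_W is inverted by pseudo-inverse.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    mu = X.mean(axis=0)
    classes = np.unique(y)
    d = X.shape[1]
    S_W = np.zeros((d, d))
    S_B = np.zeros((d, d))
    for k in classes:
        Xk = X[y == k]
        mu_k = Xk.mean(axis=0)
        dk = Xk - mu_k
        S_W += dk.T @ dk
        db = (mu_k - mu)[:, None]
        S_B += Xk.shape[0] * (db @ db.T)
    evals, evecs = np.linalg.eig(np.linalg.pinv(S_W) @ S_B)
    order = np.argsort(-evals.real)
    return S_W, S_B, evals.real[order], evecs.real[:, order]


class _WrappedClassifier(BaseEstimator, ClassifierMixin):
    """Shared plumbing: label handling plus delegation to an inner model."""

    def _make_inner(self):
        raise NotImplementedError

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        self.inner_ = self._make_inner()
        self.inner_.fit(X, self._encoder.transform(y))
        return self

    def predict_proba(self, X):
        X = check_array(X, dtype=float)
        return self.inner_.predict_proba(X)

    def predict(self, X):
        return self._encoder.inverse_transform(
            np.argmax(self.predict_proba(X), axis=1)
        )


class LinearDiscriminantClassifier(_WrappedClassifier):
    """LDA: projects onto the eigenvectors of inv(S_W) S_B that maximise
    between-class relative to within-class scatter.

    Fitted attributes expose the scatter matrices and eigenpairs computed
    directly from the training data; classification is the standard linear
    discriminant score.
    """

    def __init__(self, solver: str = "svd", shrinkage=None):
        self.solver = solver
        self.shrinkage = shrinkage

    def _make_inner(self):
        return LinearDiscriminantAnalysis(solver=self.solver, shrinkage=self.shrinkage)

    def fit(self, X, y):
        super().fit(X, y)
        (self.within_scatter_, self.between_scatter_,
         self.eigenvalues_, self.eigenvectors_) = scatter_matrices(X, y)
        self.priors_ = self.inner_.priors_
        self.means_ = self.inner_.means_
        return self


class QuadraticDiscriminantClassifier(_WrappedClassifier):
    """QDA: per-class Gaussian densities with covariance shrunk by
    ``reg_param`` toward identity variance; posteriors by Bayes rule."""

    def __init__(self, reg_param: float = 0.0):
        self.reg_param = reg_param

    def _make_inner(self):
        return QuadraticDiscriminantAnalysis(
            reg_param=self.reg_param, store_covariance=True
        )

    def fit(self, X, y):
        super().fit(X, y)
        self.priors_ = self.inner_.priors_
        self.means_ = self.inner_.means_
        self.covariances_ = self.inner_.covariance_
        return self


# ---------------------------------------------------------------------------
# multinomial logistic regression (reference-class softmax)
# ---------------------------------------------------------------------------

class MultinomialLogisticRegression(BaseEstimator, ClassifierMixin):
    """Softmax regression with K-1 weight vectors and the last class as
    reference:

        P(y = k | x) = exp(w_k.x) / (1 + sum_j exp(w_j.x)),  j = 1..K-1,

    with the reference class taking the leftover mass.  ``C`` is the inverse
    regularisation strength (penalty (1/2C)||W||^2 for L2, (1/C)||W||_1 for
    L1, intercepts unpenalised).  L2 is solved by L-BFGS-B; L1 by the same
    solver on the split w = u - v, u, v >= 0 reformulation.
    """

    def __init__(self, penalty: str = "l2", C: float = 1.0,
                 fit_intercept: bool = True, tol: float = 1e-4,
                 max_iter: int = 1000):
        self.penalty = penalty
        self.C = C
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ---------------------------------------------------------
    def _design(self, X):
        if self.fit_intercept:
            return np.hstack([X, np.ones((X.shape[0], 1))])
        return X

    def _nll_grad(self, W, Xd, Y):
        """Unpenalised negative log-likelihood and gradient.

        W: (K-1, d) weights; Y: integer labels with K-1 as reference.
        """
        n = Xd.shape[0]
        z = Xd @ W.T                                   # (n, K-1)
        zfull = np.hstack([z, np.zeros((n, 1))])
        zmax = zfull.max(axis=1, keepdims=True)
        logZ = zmax[:, 0] + np.log(np.exp(zfull - zmax).sum(axis=1))
        picked = np.where(Y < W.shape[0], np.take_along_axis(
            zfull, Y[:, None], axis=1)[:, 0], 0.0)
        nll = float(np.sum(logZ - picked))
        P = np.exp(zfull - logZ[:, None])              # (n, K)
        G = P[:, : W.shape[0]].copy()
        for k in range(W.shape[0]):
            G[Y == k, k] -= 1.0
        grad = G.T @ Xd
        return nll, grad

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        Y = self._encoder.transform(y)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes")
        Xd = self._design(X)
        d = Xd.shape[1]
        m = (K - 1) * d
        pen_mask = np.ones((K - 1, d))
        if self.fit_intercept:
            pen_mask[:, -1] = 0.0

        if self.penalty == "l2":
            def obj(w):
                W = w.reshape(K - 1, d)
                nll, g = self._nll_grad(W, Xd, Y)
                nll += np.sum((pen_mask * W) ** 2) / (2 * self.C)
                g = g + pen_mask * W / self.C
                return nll, g.ravel()

            res = minimize(obj, np.zeros(m), jac=True, method="L-BFGS-B",
                           options={"maxiter": self.max_iter,
                                    "gtol": self.tol * 1e-2,
                                    "ftol": 1e-12})
            W = res.x.reshape(K - 1, d)
        elif self.penalty == "l1":
            def obj(uv):
                u, v = uv[:m].reshape(K - 1, d), uv[m:].reshape(K - 1, d)
                W = u - v
                nll, g = self._nll_grad(W, Xd, Y)
                nll += np.sum(pen_mask * (u + v)) / self.C
                gu = g + pen_mask / self.C
                gv = -g + pen_mask / self.C
                return nll, np.concatenate([gu.ravel(), gv.ravel()])

            res = minimize(obj, np.zeros(2 * m), jac=True, method="L-BFGS-B",
                           bounds=[(0, None)] * (2 * m),
                           options={"maxiter": self.max_iter,
                                    "gtol": self.tol * 1e-2,
                                    "ftol": 1e-12})
            W = (res.x[:m] - res.x[m:]).reshape(K - 1, d)
        else:
            raise ValueError("penalty must be 'l1' or 'l2'")

        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        if self.fit_intercept:
            self.coef_ = W[:, :-1]
            self.intercept_ = W[:, -1]
        else:
            self.coef_ = W
            self.intercept_ = np.zeros(K - 1)
        return self

    def decision_function(self, X):
        X = check_array(X, dtype=float)
        return X @ self.coef_.T + self.intercept_

    def predict_proba(self, X):
        z = self.decision_function(X)
        zfull = np.hstack([z, np.zeros((z.shape[0], 1))])
        zfull -= zfull.max(axis=1, keepdims=True)
        e = np.exp(zfull)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self._encoder.inverse_transform(
            np.argmax(self.predict_proba(X), axis=1)
        )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

class RandomForestFingerClassifier(_WrappedClassifier):
    """Bagged decision-tree ensemble with feature subsampling."""

    def __init__(self, n_estimators: int = 100, max_depth=None,
                 min_samples_split: int = 2, min_samples_leaf: int = 1,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _make_inner(self):
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        )

    @property
    def feature_importances_(self):
        return self.inner_.feature_importances_


class XGBoostFingerClassifier(_WrappedClassifier):
    """Gradient-boosted trees minimising multi-class cross-entropy.

    ``max_depth=None`` means unlimited depth (mapped to the library's
    depth-0 convention under the histogram tree method).
    """

    def __init__(self, n_estimators: int = 100, max_depth=None,
                 learning_rate: float = 0.1, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _make_inner(self):
        return xgb.XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=0 if self.max_depth is None else self.max_depth,
            learning_rate=self.learning_rate,
            tree_method="hist",
            grow_policy="lossguide",
            objective="multi:softprob",
            random_state=self.random_state,
            n_jobs=1,
            verbosity=0,
        )

    def train_loss_curve(self, X, y) -> np.ndarray:
        """Per-round training cross-entropy (Eq-10-style loss) for diagnostics."""
        X, y = check_X_y(X, y, dtype=float)
        enc = LabelEncoder().fit(y)
        model = self._make_inner()
        model.set_params(eval_metric="mlogloss")
        yi = enc.transform(y)
        model.fit(X, yi, eval_set=[(X, yi)], verbose=False)
        return np.asarray(model.evals_result()["validation_0"]["mlogloss"])


# ---------------------------------------------------------------------------
# deep estimators
# ---------------------------------------------------------------------------

class _DeepClassifier(BaseEstimator, ClassifierMixin):
    """Common fit/predict plumbing for the five deep architectures."""

    _schedule = "cyclic"

    def __init__(self, max_epochs: int = 500, patience: int = 20,
                 batch_size: int = 32, l2: float = 1e-4,
                 val_fraction: float = 0.1, random_state: int = 0):
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.l2 = l2
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _build(self, input_len: int, n_classes: int, rng):
        raise NotImplementedError

    def _plan(self) -> TrainingPlan:
        return TrainingPlan(
            batch_size=self.batch_size,
            lr_schedule=self._schedule,
            l2=self.l2,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(X.shape[1], len(self.classes_), rng)
        self.history_ = train_deep(
            self.net_, X, self._encoder.transform(y), self._plan()
        )
        return self

    def predict_proba(self, X):
        X = check_array(X, dtype=float)
        return predict_proba_net(self.net_, X)

    def predict(self, X):
        return self._encoder.inverse_transform(
            np.argmax(self.predict_proba(X), axis=1)
        )


class DNNClassifier(_DeepClassifier):
    """Dense baseline (1024/512/128/64 + output), cyclic learning rate."""

    _schedule = "cyclic"

    def _build(self, input_len, n_classes, rng):
        return build_baseline_dnn(input_len, n_classes, rng)


class LSTMClassifier(_DeepClassifier):
    """Two-layer LSTM(50) stack, fixed 1e-4 learning rate."""

    _schedule = "fixed"

    def __init__(self, max_epochs: int = 500, patience: int = 20,
                 batch_size: int = 32, l2: float = 1e-4,
                 val_fraction: float = 0.1, random_state: int = 0,
                 literal_cell: bool = False):
        super().__init__(max_epochs, patience, batch_size, l2,
                         val_fraction, random_state)
        self.literal_cell = literal_cell

    def _build(self, input_len, n_classes, rng):
        return build_lstm(input_len, n_classes, rng, literal_cell=self.literal_cell)


class BiLSTMClassifier(_DeepClassifier):
    """Three bidirectional LSTM layers (50/50/20), fixed 1e-4 rate."""

    _schedule = "fixed"

    def _build(self, input_len, n_classes, rng):
        return build_bilstm(input_len, n_classes, rng)


class HybridClassifier(_DeepClassifier):
    """Parallel CNN and LSTM heads, fixed 1e-4 rate."""

    _schedule = "fixed"

    def _build(self, input_len, n_classes, rng):
        return build_hybrid(input_len, n_classes, rng)


class HemoNetClassifier(_DeepClassifier):
    """Inception-style Hemo-Net, cyclic learning rate."""

    _schedule = "cyclic"

    def __init__(self, max_epochs: int = 500, patience: int = 20,
                 batch_size: int = 32, l2: float = 1e-4,
                 val_fraction: float = 0.1, random_state: int = 0,
                 n_filters: int = 32, bottleneck: int = 32,
                 residual: bool = True):
        super().__init__(max_epochs, patience, batch_size, l2,
                         val_fraction, random_state)
        self.n_filters = n_filters
        self.bottleneck = bottleneck
        self.residual = residual

    def _build(self, input_len, n_classes, rng):
        return build_hemo_net(input_len, n_classes,
                              n_filters=self.n_filters,
                              bottleneck=self.bottleneck,
                              residual=self.residual, rng=rng)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def grid_search_cv(estimator, grid, X, y, folds: int = 5, seed: int = 0):
    """Exhaustive stratified 5-fold grid search on validation accuracy.

    Ties are broken by first-in-grid order.  Returns
    (refit best estimator, best params, CV table as a DataFrame).
    """
    X, y = check_X_y(X, y, dtype=float)
    if isinstance(grid, dict) and not grid:
        raise ValueError("empty hyperparameter grid")
    if isinstance(grid, list) and not any(grid):
        raise ValueError("empty hyperparameter grid")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} members for {folds}-fold CV "
            f"(smallest has {counts.min()})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(estimator, grid, scoring="accuracy", cv=cv, refit=True)
    gs.fit(X, y)
    table = pd.DataFrame(gs.cv_results_)[
        ["params", "mean_test_score", "std_test_score", "rank_test_score"]
    ]
    return gs.best_estimator_, gs.best_params_, table


def fit_lda(X, y, folds: int = 5, seed: int = 0):
    return grid_search_cv(LinearDiscriminantClassifier(), LDA_GRID, X, y, folds, seed)


def fit_qda(X, y, folds: int = 5, seed: int = 0):
    return grid_search_cv(QuadraticDiscriminantClassifier(), QDA_GRID, X, y, folds, seed)


def fit_mnlr(X, y, folds: int = 5, seed: int = 0):
    return grid_search_cv(MultinomialLogisticRegression(), MNLR_GRID, X, y, folds, seed)


def fit_forest(X, y, folds: int = 5, seed: int = 0):
    return grid_search_cv(
        RandomForestFingerClassifier(random_state=seed), RF_GRID, X, y, folds, seed
    )


def fit_boost(X, y, folds: int = 5, seed: int = 0):
    return grid_search_cv(
        XGBoostFingerClassifier(random_state=seed), XGB_GRID, X, y, folds, seed
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

MODEL_REGISTRY: dict[str, type] = {
    "lda": LinearDiscriminantClassifier,
    "qda": QuadraticDiscriminantClassifier,
    "mnlr": MultinomialLogisticRegression,
    "rf": RandomForestFingerClassifier,
    "xgboost": XGBoostFingerClassifier,
    "dnn": DNNClassifier,
    "lstm": LSTMClassifier,
    "bilstm": BiLSTMClassifier,
    "hybrid": HybridClassifier,
    "hemonet": HemoNetClassifier,
}


def make_model(name: str, **params):
    """Instantiate a registered model by name."""
    try:
        cls = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None
    return cls(**params)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_ARCHIVE_FORMAT = 1


def save_model(model, path) -> None:
    """Serialize a fitted model (config + weights) to a versioned archive."""
    import joblib

    joblib.dump({"format_version": _ARCHIVE_FORMAT,
                 "class": type(model).__name__,
                 "params": model.get_params(),
                 "model": model}, path)


def load_model(path):
    """Load a model archive written by :func:`save_model`."""
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != _ARCHIVE_FORMAT:
        raise ValueError(
            f"unsupported model archive version {payload.get('format_version')!r}"
        )
    return payload["model"]
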