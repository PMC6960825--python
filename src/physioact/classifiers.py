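"""Classifier suite under a uniform fit/predict contract.

The least-squares linear and quadratic classifiers (LSLC/LSQC) and the
centroid-displacement nearest-neighbour rule (CDNN) are implemented here;
kNN, linear/RBF SVM (one-against-all), MLP (one hidden layer of 8/12/16
units with early stopping) and Random Forest (200 CART trees, no pruning)
wrap scikit-learn estimators.

All classifiers expect feature matrices already z-scored with design-set
statistics (the evaluation pipeline owns normalization).
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC

RIDGE = 1e-8  # numerical-safety ridge on the normal equations


def one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def quadratic_expand(X: np.ndarray) -> np.ndarray:
    """Features, their squares and all pairwise products (no intercept —
    the linear solver appends one)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    cross = [X[:, i] * X[:, j] for i, j in itertools.combinations(range(d), 2)]
    parts = [X, X ** 2] + ([np.column_stack(cross)] if cross else [])
    return np.hstack(parts)


class LeastSquaresClassifier:
    """Multi-class linear discriminants fitted by least squares against
    one-hot {0,1} targets (the Wiener–Hopf / normal-equation solution).

    ``quadratic=True`` fits the same model on the quadratic expansion of
    the inputs (the LSQC).  ``design_mse_`` is the resubstitution mean
    squared error of the discriminant outputs, the quantity the GA wrapper
    uses as fitness.
    """

    def __init__(self, quadratic: bool = False, ridge: float = RIDGE) -> None:
        self.quadratic = quadratic
        self.ridge = ridge

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.quadratic:
            X = quadratic_expand(X)
        return np.hstack([X, np.ones((len(X), 1))])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LeastSquaresClassifier":
        Xa = self._design(X)
        self.classes_ = np.unique(y)
        Y = one_hot(np.asarray(y), self.classes_)
        G = Xa.T @ Xa + self.ridge * np.eye(Xa.shape[1])
        try:
            self.W_ = np.linalg.solve(G, Xa.T @ Y)
        except np.linalg.LinAlgError:  # rank deficient: minimum-norm solve
            self.W_ = np.linalg.lstsq(Xa, Y, rcond=None)[0]
        resid = Xa @ self.W_ - Y
        self.design_mse_ = float(np.mean(resid ** 2))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._design(X) @ self.W_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class CDNN:
    """Centroid-displacement k-nearest-neighbour rule.

    Among the k Euclidean nearest design patterns, each class's neighbour
    centroid is computed with and without the test pattern; the class whose
    centroid moves least wins.  For m same-class neighbours with centroid c
    the displacement is ||x - c|| / (m + 1).  Ties go to the lowest class
    index (classes sorted)."""

    def __init__(self, k: int = 5) -> None:
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CDNN":
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        self.classes_ = np.unique(self.y_)
        if self.k > len(self.X_):
            raise ValueError("k exceeds design-set size")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for x in X:
            d = np.linalg.norm(self.X_ - x, axis=1)
            nn = np.argsort(d, kind="stable")[: self.k]
            labels = self.y_[nn]
            best_cls, best_disp = None, np.inf
            for cls in self.classes_:
                m = labels == cls
                if not np.any(m):
                    continue
                pts = self.X_[nn][m]
                c = pts.mean(axis=0)
                disp = np.linalg.norm(x - c) / (len(pts) + 1)
                if disp < best_disp - 1e-15:
                    best_cls, best_disp = cls, disp
            out.append(best_cls)
        return np.asarray(out)


class MajorityClassifier:
    """Chance-level control: always predicts the most frequent design class
    (ties to the lowest class index).  On a balanced M-class problem its
    error is 1 - 1/M."""

    def fit(self, X, y):
        classes, counts = np.unique(y, return_counts=True)
        self.classes_ = classes
        self.majority_ = classes[int(np.argmax(counts))]
        return self

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.majority_)


class RandomForestLogF(RandomForestClassifier):
    """Random forest with F = floor(log2(d) + 1) candidate features per
    node, d being the number of input features; 200 unpruned CART trees,
    each grown on the full design set (sampling without replacement)."""

    def __init__(self, n_estimators: int = 200, random_state=None):
        super().__init__(n_estimators=n_estimators, bootstrap=False,
                         random_state=random_state)

    def fit(self, X, y, sample_weight=None):
        self.max_features = rf_max_features(np.asarray(X).shape[1])
        return super().fit(X, y, sample_weight=sample_weight)


def rf_max_features(n_features: int) -> int:
    """F = floor(log2(d) + 1), capped to [1, d]."""
    f = int(np.floor(np.log2(n_features) + 1)) if n_features >= 1 else 1
    return max(1, min(f, n_features))


# ---------------------------------------------------------------------------
# factory + hyperparameter selection
# ---------------------------------------------------------------------------

CLASSIFIER_KINDS = ("lslc", "lsqc", "knn", "cdnn", "linsvm", "rbfsvm",
                    "mlp8", "mlp12", "mlp16", "rf")


def make_classifier(kind: str, seed: int | None = None, **hp):
    """Instantiate a classifier by kind name.  Stochastic learners (MLP, RF)
    take an explicit seed; the rest are seed-free."""
    if kind == "lslc":
        return LeastSquaresClassifier()
    if kind == "lsqc":
        return LeastSquaresClassifier(quadratic=True)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    if kind == "cdnn":
        return CDNN(k=hp.get("k", 5))
    if kind == "linsvm":
        return LinearSVC(C=hp.get("C", 1.0))
    if kind == "rbfsvm":
        return OneVsRestClassifier(
            SVC(kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale")))
    if kind.startswith("mlp"):
        hidden = int(kind[3:])
        # learning rate tuned for z-scored inputs (the pipeline contract)
        return MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=500,
                             early_stopping=True, validation_fraction=0.2,
                             n_iter_no_change=10, learning_rate_init=0.01,
                             random_state=seed)
    if kind == "rf":
        return RandomForestLogF(n_estimators=hp.get("n_estimators", 200),
                                random_state=seed)
    if kind == "majority":
        return MajorityClassifier()
    raise ValueError(f"unknown classifier kind {kind!r}")


def default_grid(kind: str, X: np.ndarray | None = None) -> list[dict]:
    """Hyperparameter grids, ordered simplest-first so CV ties break toward
    the lower-complexity point."""
    if kind in ("knn", "cdnn"):
        return [{"k": k} for k in range(1, 26, 2)]
    if kind == "linsvm":
        return [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)]
    if kind == "rbfsvm":
        if X is not None and len(X) > 1:
            idx = np.random.default_rng(0).choice(len(X), min(len(X), 200),
                                                  replace=False)
            sub = np.asarray(X)[idx]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
            med = float(np.median(d[d > 0])) or 1.0
        else:
            med = 1.0
        grid = []
        for c in (0.1, 1.0, 10.0, 100.0):
            for s in (0.5, 1.0, 2.0, 4.0):
                grid.append({"C": c, "gamma": 1.0 / (2 * (s * med) ** 2)})
        return grid
    return [{}]


def select_hyperparameters(kind, X: np.ndarray, y: np.ndarray,
                           groups: np.ndarray, grid: list[dict],
                           seed: int | None = None):
    """Subject-wise cross-validation over the design set: each design
    subject serves once as a validation fold; the grid point with the
    lowest mean validation error wins, ties going to the earlier (simpler)
    grid entry.  ``kind`` may be a kind name or a factory
    ``f(seed=..., **params) -> estimator``."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    factory = kind if callable(kind) else (
        lambda seed=None, **hp: make_classifier(kind, seed=seed, **hp))
    uniq = np.unique(groups)
    errors = np.zeros(len(grid))
    for g in uniq:
        val = groups == g
        Xd, yd = X[~val], y[~val]
        Xv, yv = X[val], y[val]
        for j, params in enumerate(grid):
            model = factory(seed=seed, **params)
            model.fit(Xd, yd)
            errors[j] += np.mean(model.predict(Xv) != yv)
    return grid[int(np.argmin(errors))]
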