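"""Weighted varied-granularity scanning and the cascade deep forest.

The transform turns a feature vector ``F`` of length ``n`` into
window-level sub-instances: a frame of length ``m`` slides with stride 1
over both the feature vector and the per-feature weight vector, the two
resulting ``(n−m+1, m)`` matrices are multiplied elementwise (so
high-weight features dominate their windows), and every weighted window
is scored by two forest scanners — a completely-random-trees forest and
an ordinary random forest.  Their class-probability outputs are
concatenated row-major into a single vector of length ``4(n−m+1)``
(``2(n−m+1)`` for regression, one prediction per window per scanner),
which feeds a cascade forest: stacked layers whose class-probability
outputs augment the next layer's input, grown until an out-of-fold
estimate of performance stops improving.

The per-feature weights come from Gini-impurity importance of an
auxiliary forest and are computed once on the training data, then frozen
for every later transform.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import accuracy_score, mean_squared_error
from sklearn.model_selection import cross_val_predict
from sklearn.utils.validation import check_is_fitted, check_X_y

from .weighting import GiniFeatureWeighter

__all__ = [
    "window_slices",
    "hadamard_weight",
    "scan_transform",
    "WeightedDeepForestClassifier",
    "WeightedDeepForestRegressor",
    "fit_weighted_deep_forest",
]


def window_slices(feature_vec, weight_vec, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 frames of length ``m`` over a feature and a weight vector.

    Row ``j`` of each output holds entries ``j .. j+m−1``; both matrices
    have shape ``(n − m + 1, m)``.
    """
    f = np.asarray(feature_vec, dtype=float).ravel()
    w = np.asarray(weight_vec, dtype=float).ravel()
    n = f.size
    if w.size != n:
        raise ValueError(f"feature and weight vectors differ in length ({n} vs {w.size})")
    if m < 1 or m > n:
        raise ValueError(f"window length must satisfy 1 <= m <= n ({m} vs n={n})")
    return (
        np.lib.stride_tricks.sliding_window_view(f, m).copy(),
        np.lib.stride_tricks.sliding_window_view(w, m).copy(),
    )


def hadamard_weight(f: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Elementwise product of the window matrices, ``f_pre = f ⊙ w``."""
    f = np.asarray(f, dtype=float)
    w = np.asarray(w, dtype=float)
    if f.shape != w.shape:
        raise ValueError(f"shape mismatch {f.shape} vs {w.shape}")
    return f * w


def scan_transform(f_pre: np.ndarray, scanner_a, scanner_b) -> np.ndarray:
    """Score each weighted window with both scanners and concatenate.

    For classifiers the output is ``f_a.ravel() ‖ f_b.ravel()`` where
    each block is ``(n−m+1, 2)`` class probabilities — total length
    ``4(n−m+1)``.  Regressor scanners contribute one value per window.
    """
    check_is_fitted(scanner_a)
    check_is_fitted(scanner_b)
    f_pre = np.asarray(f_pre, dtype=float)
    blocks = []
    for scanner in (scanner_a, scanner_b):
        if hasattr(scanner, "predict_proba"):
            blocks.append(scanner.predict_proba(f_pre))
        else:
            blocks.append(scanner.predict(f_pre).reshape(-1, 1))
    return np.concatenate([b.ravel() for b in blocks])


class _WeightedDeepForestBase(BaseEstimator):
    """Shared fit/transform machinery of the classifier and regressor."""

    def __init__(
        self,
        window: int | None = None,
        n_scanner_estimators: int = 30,
        n_cascade_estimators: int = 50,
        max_layers: int = 5,
        patience: int = 2,
        cv: int = 3,
        weight_convention: str = "weighted",
        n_weight_estimators: int = 100,
        random_state: int | None = None,
    ):
        self.window = window
        self.n_scanner_estimators = n_scanner_estimators
        self.n_cascade_estimators = n_cascade_estimators
        self.max_layers = max_layers
        self.patience = patience
        self.cv = cv
        self.weight_convention = weight_convention
        self.n_weight_estimators = n_weight_estimators
        self.random_state = random_state

    # subclass hooks -------------------------------------------------
    _task: str  # "classification" | "regression"

    def _make_scanner(self, kind: str, seed: int):
        raise NotImplementedError

    def _make_cascade_forest(self, kind: str, seed: int):
        raise NotImplementedError

    def _layer_output(self, forest, X):
        """Per-forest output used to augment the next layer's input."""
        raise NotImplementedError

    def _oof_layer_output(self, forest, X, y, seed):
        raise NotImplementedError

    def _score(self, y, layer_outputs) -> float:
        """Higher-is-better score of the averaged layer outputs."""
        raise NotImplementedError

    # ----------------------------------------------------------------
    def _resolved_window(self, n_features: int) -> int:
        if self.window is not None:
            return int(self.window)
        return int(np.ceil(np.sqrt(n_features)))

    def _windows_of(self, X: np.ndarray) -> np.ndarray:
        """Stack per-sample weighted window matrices into one 2-D array."""
        rows = []
        for x in X:
            f, w = window_slices(x, self.weights_, self.window_)
            rows.append(hadamard_weight(f, w))
        return np.vstack(rows)

    def _scan(self, X: np.ndarray) -> np.ndarray:
        """Weighted-scanning representation, one F_out row per sample."""
        X = np.asarray(X, dtype=float)
        return np.vstack(
            [
                scan_transform(
                    hadamard_weight(*window_slices(x, self.weights_, self.window_)),
                    self.scanner_a_,
                    self.scanner_b_,
                )
                for x in X
            ]
        )

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), y)
        if self._task == "classification" and len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        rng = np.random.RandomState(self.random_state)
        seeds = rng.randint(0, 2**31 - 1, size=4 + 2 * self.max_layers)

        self.window_ = self._resolved_window(X.shape[1])
        self.n_windows_ = X.shape[1] - self.window_ + 1

        # per-feature weights, computed once on the training data and frozen
        weighter = GiniFeatureWeighter(
            n_estimators=self.n_weight_estimators,
            convention=self.weight_convention,
            task=self._task,
            random_state=int(seeds[0]),
        ).fit(X, y)
        self.weighter_ = weighter
        self.weights_ = weighter.weights_

        # window-level scanners; windows inherit the parent instance label
        win_X = self._windows_of(X)
        win_y = np.repeat(y, self.n_windows_)
        self.scanner_a_ = self._make_scanner("random", int(seeds[1])).fit(win_X, win_y)
        self.scanner_b_ = self._make_scanner("forest", int(seeds[2])).fit(win_X, win_y)

        F_out = self._scan(X)

        # cascade: grow layers while the out-of-fold score improves
        self.layers_ = []
        layer_scores = []
        best_score, best_depth, stall = -np.inf, 0, 0
        current, current_oof = F_out, F_out
        for depth in range(self.max_layers):
            s_a, s_b = int(seeds[3 + 2 * depth]), int(seeds[4 + 2 * depth])
            forests = [
                self._make_cascade_forest("random", s_a),
                self._make_cascade_forest("forest", s_b),
            ]
            oof = [self._oof_layer_output(f, current_oof, y, s) for f, s in
                   zip(forests, (s_a, s_b))]
            for f in forests:
                f.fit(current, y)
            score = self._score(y, oof)
            self.layers_.append(forests)
            layer_scores.append(score)
            if score > best_score + 1e-12:
                best_score, best_depth, stall = score, depth, 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
            full = [self._layer_output(f, current) for f in forests]
            current = np.hstack([F_out] + full)
            current_oof = np.hstack([F_out] + oof)
        self.n_layers_ = best_depth + 1
        self.layers_ = self.layers_[: self.n_layers_]
        self.layer_scores_ = layer_scores
        if self._task == "classification":
            self.classes_ = np.unique(y)
        return self

    def _forward(self, X) -> list[np.ndarray]:
        """Outputs of the final cascade layer for new data."""
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights_.size:
            raise ValueError(
                f"expected {self.weights_.size} features, got {X.shape[1]}"
            )
        F_out = self._scan(X)
        current = F_out
        for depth, forests in enumerate(self.layers_):
            outputs = [self._layer_output(f, current) for f in forests]
            if depth == len(self.layers_) - 1:
                return outputs
            current = np.hstack([F_out] + outputs)
        return outputs

    def transform(self, X) -> np.ndarray:
        """Expose the weighted-scanning representation F_out."""
        check_is_fitted(self, "scanner_a_")
        return self._scan(np.asarray(X, dtype=float))


class WeightedDeepForestClassifier(_WeightedDeepForestBase, ClassifierMixin):
    """Cascade deep forest with Gini-weighted varied-granularity scanning.

    Parameters
    ----------
    window : int or None, default=None
        Scanning frame length ``m``.  Use 3 for trinucleotide-style
        encoded sequences; ``None`` picks ``ceil(sqrt(n_features))``,
        suited to unordered numeric tables.
    n_scanner_estimators, n_cascade_estimators : int
        Trees per scanner forest and per cascade-layer forest.
    max_layers : int, default=5
        Hard cap on cascade depth.
    patience : int, default=2
        Stop growing after this many layers without improvement of the
        out-of-fold accuracy.
    cv : int, default=3
        Folds for the out-of-fold layer estimates.
    weight_convention : {"weighted", "as_printed"}
        Node-score convention of the Gini feature weighting.
    random_state : int or None
        Seeds every forest; fixed seed + fixed data gives identical
        predictions.
    """

    _task = "classification"

    def _make_scanner(self, kind: str, seed: int):
        if kind == "random":
            return ExtraTreesClassifier(
                n_estimators=self.n_scanner_estimators,
                max_features=1,
                random_state=seed,
                n_jobs=1,
            )
        return RandomForestClassifier(
            n_estimators=self.n_scanner_estimators, random_state=seed, n_jobs=1
        )

    def _make_cascade_forest(self, kind: str, seed: int):
        if kind == "random":
            return ExtraTreesClassifier(
                n_estimators=self.n_cascade_estimators,
                max_features=1,
                random_state=seed,
                n_jobs=1,
            )
        return RandomForestClassifier(
            n_estimators=self.n_cascade_estimators, random_state=seed, n_jobs=1
        )

    def _layer_output(self, forest, X):
        return forest.predict_proba(X)

    def _oof_layer_output(self, forest, X, y, seed):
        return cross_val_predict(forest, X, y, cv=self.cv, method="predict_proba")

    def _score(self, y, layer_outputs) -> float:
        mean_proba = np.mean(layer_outputs, axis=0)
        return accuracy_score(y, np.argmax(mean_proba, axis=1))

    def predict_proba(self, X) -> np.ndarray:
        return np.mean(self._forward(X), axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class WeightedDeepForestRegressor(_WeightedDeepForestBase, RegressorMixin):
    """Regression cascade forest with variance-reduction feature weights.

    Scanners and cascade forests are regressor ensembles; each scanner
    contributes one prediction per window, so the scanned representation
    has length ``2(n−m+1)``.  Layer growth stops when the out-of-fold
    mean squared error stops decreasing.
    """

    _task = "regression"

    def _make_scanner(self, kind: str, seed: int):
        if kind == "random":
            return ExtraTreesRegressor(
                n_estimators=self.n_scanner_estimators,
                max_features=1,
                random_state=seed,
                n_jobs=1,
            )
        return RandomForestRegressor(
            n_estimators=self.n_scanner_estimators, random_state=seed, n_jobs=1
        )

    def _make_cascade_forest(self, kind: str, seed: int):
        if kind == "random":
            return ExtraTreesRegressor(
                n_estimators=self.n_cascade_estimators,
                max_features=1,
                random_state=seed,
                n_jobs=1,
            )
        return RandomForestRegressor(
            n_estimators=self.n_cascade_estimators, random_state=seed, n_jobs=1
        )

    def _layer_output(self, forest, X):
        return forest.predict(X).reshape(-1, 1)

    def _oof_layer_output(self, forest, X, y, seed):
        return cross_val_predict(forest, X, y, cv=self.cv).reshape(-1, 1)

    def _score(self, y, layer_outputs) -> float:
        pred = np.mean(layer_outputs, axis=0).ravel()
        return -mean_squared_error(y, pred)

    def predict(self, X) -> np.ndarray:
        return np.mean(self._forward(X), axis=0).ravel()


def fit_weighted_deep_forest(X, y, config: dict | None = None, seed: int | None = None):
    """Fit a weighted deep forest; task inferred from the target dtype.

    ``config`` keys are passed to the estimator; floating-point targets
    select the regressor, everything else the classifier.
    """
    y_arr = np.asarray(y)
    is_regression = np.issubdtype(y_arr.dtype, np.floating) and not np.array_equal(
        y_arr, y_arr.astype(int)
    )
    cls = WeightedDeepForestRegressor if is_regression else WeightedDeepForestClassifier
    return cls(random_state=seed, **(config or {})).fit(X, y_arr)
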