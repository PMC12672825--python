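"""Optimum-decision model selection over three candidate families.

Given a preprocessed dataset and a task flag (0 = classification,
1 = regression), the framework tunes a Random Forest and an XGBoost
model with a seeded interval-refining random search, fits the weighted
deep forest with its defaults, evaluates every candidate, and returns
the best as the final predictor.

The hyperparameter search runs in cycles: each cycle samples
configurations uniformly inside the current bounds, scores them by
k-fold cross-validation on the training portion, and then shrinks the
bounds around the best configuration found so far, so later cycles probe
an increasingly narrow region.  The held-out validation split is used
only for the final candidate comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier, XGBRegressor

from .metrics import classification_report, regression_report
from .scanning import WeightedDeepForestClassifier, WeightedDeepForestRegressor

__all__ = [
    "TaskSpec",
    "CandidateRecord",
    "SelectionResult",
    "SEARCH_SPACES",
    "refine_search",
    "tune",
    "train_candidates",
    "select_best",
    "predict",
    "OptimDase",
]

CLASSIFICATION, REGRESSION = 0, 1

# direction of each ranking metric
_METRIC_DIRECTION = {
    "accuracy": 1,
    "auc": 1,
    "f1": 1,
    "precision": 1,
    "recall": 1,
    "rmse": -1,
    "mae": -1,
    "pcc": 1,
    "varscore": 1,
}


@dataclass(frozen=True)
class TaskSpec:
    """Task selector: flag 0 = classification, 1 = regression.

    ``metric_priority`` orders the metrics used to rank candidates;
    later entries break ties in earlier ones.
    """

    flag: int
    metric_priority: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.flag not in (CLASSIFICATION, REGRESSION):
            raise ValueError("flag must be 0 (classification) or 1 (regression)")
        if not self.metric_priority:
            default = (
                ("accuracy", "auc", "f1")
                if self.flag == CLASSIFICATION
                else ("rmse", "pcc")
            )
            object.__setattr__(self, "metric_priority", default)
        unknown = set(self.metric_priority) - set(_METRIC_DIRECTION)
        if unknown:
            raise ValueError(f"unknown metrics in priority: {sorted(unknown)}")

    @property
    def is_classification(self) -> bool:
        return self.flag == CLASSIFICATION


@dataclass
class CandidateRecord:
    name: str
    params: dict[str, Any]
    cv_score: float | None = None
    validation_metrics: dict[str, float] = field(default_factory=dict)
    model: Any = None
    failed: bool = False
    error: str | None = None


@dataclass
class SelectionResult:
    """Winning model plus the full per-candidate evaluation record."""

    best_model: Any
    best_name: str
    records: list[CandidateRecord]
    task: TaskSpec
    ranking: list[str] = field(default_factory=list)


# hyperparameter bounds bracket the values the tuned models land on in
# practice: trees 50-2000, depth 1-25, learning rate 1e-3-0.3 (log scale)
SEARCH_SPACES: dict[str, dict[str, tuple[str, float, float]]] = {
    "random_forest": {
        "n_estimators": ("int", 50, 2000),
        "max_depth": ("int", 1, 25),
    },
    "xgboost": {
        "n_estimators": ("int", 50, 2000),
        "max_depth": ("int", 1, 25),
        "learning_rate": ("logfloat", 1e-3, 0.3),
    },
}


def _sample_params(rng: np.random.RandomState, space) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "int":
            out[name] = int(rng.randint(int(lo), int(hi) + 1))
        elif kind == "float":
            out[name] = float(rng.uniform(lo, hi))
        elif kind == "logfloat":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
    return out


def _shrink_space(space, best: dict[str, Any], factor: float):
    """Narrow every bound around the current best, clipped to the original."""
    new = {}
    for name, (kind, lo, hi) in space.items():
        center = best[name]
        if kind == "logfloat":
            log_lo, log_hi = np.log(lo), np.log(hi)
            half = (log_hi - log_lo) * factor / 2
            c = np.log(center)
            new_lo = float(np.exp(max(log_lo, c - half)))
            new_hi = float(np.exp(min(log_hi, c + half)))
        else:
            half = (hi - lo) * factor / 2
            new_lo = max(lo, center - half)
            new_hi = min(hi, center + half)
        if kind == "int" and int(new_hi) < int(new_lo) + 1:
            new_hi = new_lo + 1
        new[name] = (kind, new_lo, new_hi)
    return new


def refine_search(
    objective: Callable[[dict[str, Any]], float],
    space: dict[str, tuple[str, float, float]],
    n_trials: int,
    seed: int | None = None,
    n_cycles: int = 4,
    shrink: float = 0.5,
) -> tuple[dict[str, Any], float]:
    """Cyclic random search with interval refinement; maximizes ``objective``.

    The trial budget is split across ``n_cycles`` cycles; after each
    cycle the sampling bounds contract by ``shrink`` around the best
    configuration seen so far.  Fully seeded.
    """
    if not space:
        raise ValueError("empty search space")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.RandomState(seed)
    n_cycles = max(1, min(n_cycles, n_trials))
    per_cycle = math.ceil(n_trials / n_cycles)
    best_params, best_score = None, -np.inf
    current = dict(space)
    done = 0
    for _ in range(n_cycles):
        for _ in range(min(per_cycle, n_trials - done)):
            params = _sample_params(rng, current)
            score = objective(params)
            done += 1
            if score > best_score:
                best_params, best_score = params, score
        if done >= n_trials:
            break
        current = _shrink_space(current, best_params, shrink)
    return best_params, best_score


def _make_model(family: str, task: TaskSpec, params: dict[str, Any], seed: int | None):
    if family == "random_forest":
        cls = RandomForestClassifier if task.is_classification else RandomForestRegressor
        return cls(random_state=seed, n_jobs=1, **params)
    if family == "xgboost":
        cls = XGBClassifier if task.is_classification else XGBRegressor
        return cls(random_state=seed, n_jobs=1, verbosity=0, tree_method="hist", **params)
    if family == "weighted_deep_forest":
        cls = (
            WeightedDeepForestClassifier
            if task.is_classification
            else WeightedDeepForestRegressor
        )
        return cls(random_state=seed, **params)
    raise ValueError(f"unknown candidate family {family!r}")


def _cv_splitter(task: TaskSpec, cv: int, seed: int | None):
    if task.is_classification:
        return StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    return KFold(n_splits=cv, shuffle=True, random_state=seed)


def tune(
    candidate_family: str,
    X,
    y,
    task: TaskSpec,
    n_trials: int = 800,
    seed: int | None = None,
    cv: int = 5,
) -> tuple[dict[str, Any], float]:
    """Tune one family's hyperparameters by cross-validated refine search.

    The objective is the mean k-fold score of the task's primary metric
    (accuracy for classification, negative RMSE for regression) on the
    training portion only.  Returns ``(best_params, best_cv_score)``.
    """
    space = SEARCH_SPACES[candidate_family]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scoring = "accuracy" if task.is_classification else "neg_root_mean_squared_error"
    splitter = _cv_splitter(task, cv, seed)

    def objective(params: dict[str, Any]) -> float:
        model = _make_model(candidate_family, task, params, seed)
        return float(np.mean(cross_val_score(model, X, y, cv=splitter, scoring=scoring)))

    return refine_search(objective, space, n_trials=n_trials, seed=seed)


def train_candidates(
    X,
    y,
    task: TaskSpec,
    n_trials: int = 800,
    seed: int | None = None,
    cv: int = 5,
    deep_forest_params: dict[str, Any] | None = None,
) -> list[CandidateRecord]:
    """Tune and fit the three candidates: RF, XGBoost, weighted deep forest.

    The deep forest uses its default hyperparameters (tuning disabled);
    a candidate that fails to fit is recorded as failed and selection
    proceeds over the survivors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    records: list[CandidateRecord] = []
    for family in ("random_forest", "xgboost", "weighted_deep_forest"):
        rec = CandidateRecord(name=family, params={})
        try:
            if family == "weighted_deep_forest":
                rec.params = dict(deep_forest_params or {})
            else:
                rec.params, rec.cv_score = tune(
                    family, X, y, task, n_trials=n_trials, seed=seed, cv=cv
                )
            model = _make_model(family, task, rec.params, seed)
            model.fit(X, y)
            rec.model = model
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            rec.failed = True
            rec.error = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    if all(r.failed for r in records):
        raise RuntimeError(
            "all candidates failed to fit: "
            + "; ".join(f"{r.name}: {r.error}" for r in records)
        )
    return records


def _evaluate(model, X_val, y_val, task: TaskSpec) -> dict[str, float]:
    if task.is_classification:
        scores = model.predict_proba(np.asarray(X_val, dtype=float))[:, 1]
        return classification_report(y_val, scores)
    preds = model.predict(np.asarray(X_val, dtype=float))
    return {k: v for k, v in regression_report(y_val, preds).items() if k != "variant"}


def _rank_key(metrics: dict[str, float], priority) -> tuple:
    return tuple(-_METRIC_DIRECTION[m] * metrics[m] for m in priority)


def select_best(
    candidates: list[CandidateRecord], X_val, y_val, task: TaskSpec
) -> SelectionResult:
    """Score fitted candidates on held-out data and pick the winner.

    Ranking follows ``task.metric_priority``: the first metric decides,
    later metrics break ties.  The winner is never dominated on every
    priority metric by another candidate.
    """
    survivors = [r for r in candidates if not r.failed]
    if not survivors:
        raise ValueError("no successfully fitted candidates to select from")
    for rec in survivors:
        rec.validation_metrics = _evaluate(rec.model, X_val, y_val, task)
    ordered = sorted(
        survivors, key=lambda r: _rank_key(r.validation_metrics, task.metric_priority)
    )
    return SelectionResult(
        best_model=ordered[0].model,
        best_name=ordered[0].name,
        records=candidates,
        task=task,
        ranking=[r.name for r in ordered],
    )


def predict(result: SelectionResult, Z) -> dict[str, np.ndarray]:
    """Apply the selected model to a test set prepared like the training data.

    Classification returns labels and positive-class probabilities;
    regression returns continuous values.  A feature-count mismatch
    against the training schema raises with the discrepancy named.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.size == 0:
        return {"labels": np.array([], dtype=int), "values": np.array([])}
    model = result.best_model
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is None and hasattr(model, "weights_"):
        n_expected = model.weights_.size
    if n_expected is not None and Z.shape[1] != n_expected:
        raise ValueError(
            f"test set has {Z.shape[1]} features but the selected model "
            f"({result.best_name}) was trained on {n_expected}"
        )
    if result.task.is_classification:
        proba = model.predict_proba(Z)[:, 1]
        return {"labels": (proba >= 0.5).astype(int), "probabilities": proba}
    return {"values": np.asarray(model.predict(Z), dtype=float)}


class OptimDase(BaseEstimator):
    """Best-of-three predictor with internal 4:1 train/validation split.

    On ``fit`` the data is split 80/20 (seeded), a tuned Random Forest,
    a tuned XGBoost and the weighted deep forest are trained on the 80%
    portion, every candidate is scored on the 20% validation portion by
    the task's metric priority, and the winner becomes the predictor.

    Parameters
    ----------
    flag : {0, 1}
        0 selects classification, 1 regression.
    n_trials : int, default=50
        Hyperparameter search budget per tuned family (the full-scale
        default used for real runs is 800; 50 is the fast profile).
    cv : int, default=5
        Folds of the tuning cross-validation.
    metric_priority : tuple of str or None
        Ranking metrics; None uses the task default
        (accuracy/auc/f1 or rmse/pcc).
    deep_forest_params : dict or None
        Overrides for the weighted deep forest (window length etc.).
    random_state : int or None

    Attributes
    ----------
    result_ : SelectionResult with the winner and all candidate records.
    best_model_, best_name_ : the selected fitted model and its family.
    """

    def __init__(
        self,
        flag: int = CLASSIFICATION,
        n_trials: int = 50,
        cv: int = 5,
        metric_priority: tuple[str, ...] | None = None,
        deep_forest_params: dict[str, Any] | None = None,
        random_state: int | None = None,
    ):
        self.flag = flag
        self.n_trials = n_trials
        self.cv = cv
        self.metric_priority = metric_priority
        self.deep_forest_params = deep_forest_params
        self.random_state = random_state

    def _task(self) -> TaskSpec:
        return TaskSpec(self.flag, tuple(self.metric_priority or ()))

    def fit(self, X, y):
        from .prep import train_validation_split  # avoid cycle at import
        import pandas as pd

        task = self._task()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        df = pd.DataFrame(X)
        df["__y__"] = y
        train, val = train_validation_split(df, seed=self.random_state or 0)
        X_tr, y_tr = train.drop(columns="__y__").to_numpy(), train["__y__"].to_numpy()
        X_va, y_va = val.drop(columns="__y__").to_numpy(), val["__y__"].to_numpy()
        if task.is_classification:
            y_tr, y_va = y_tr.astype(int), y_va.astype(int)
        candidates = train_candidates(
            X_tr,
            y_tr,
            task,
            n_trials=self.n_trials,
            seed=self.random_state,
            cv=self.cv,
            deep_forest_params=self.deep_forest_params,
        )
        self.result_ = select_best(candidates, X_va, y_va, task)
        self.best_model_ = self.result_.best_model
        self.best_name_ = self.result_.best_name
        self.n_features_in_ = X.shape[1]
        if task.is_classification:
            self.classes_ = np.unique(y.astype(int))
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        out = predict(self.result_, X)
        return out["labels"] if self._task().is_classification else out["values"]

    def predict_proba(self, X):
        check_is_fitted(self, "result_")
        if not self._task().is_classification:
            raise AttributeError("predict_proba is undefined for regression")
        return self.best_model_.predict_proba(np.asarray(X, dtype=float))
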