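"""Hyperparameter search, candidate training and best-of-three selection."""

import numpy as np
import pytest

from optimdase.select import (
    CandidateRecord,
    OptimDase,
    TaskSpec,
    predict,
    refine_search,
    select_best,
    train_candidates,
    tune,
)

FAST_DF = dict(n_scanner_estimators=8, n_cascade_estimators=10,
               n_weight_estimators=15, max_layers=1, window=3)


class _StubModel:
    """Fixed-output candidate for rigged selection scenarios."""

    def __init__(self, proba):
        self.proba = np.asarray(proba, dtype=float)
        self.n_features_in_ = 1

    def predict_proba(self, X):
        return np.column_stack([1 - self.proba, self.proba])

    def predict(self, X):
        return (self.proba >= 0.5).astype(int)


def test_taskspec_defaults_and_validation():
    assert TaskSpec(0).metric_priority == ("accuracy", "auc", "f1")
    assert TaskSpec(1).metric_priority == ("rmse", "pcc")
    with pytest.raises(ValueError):
        TaskSpec(2)
    with pytest.raises(ValueError):
        TaskSpec(0, ("nonsense",))


def test_refine_search_single_trial_returns_sample():
    space = {"x": ("float", 0.0, 1.0)}
    params, score = refine_search(lambda p: -p["x"], space, n_trials=1, seed=0)
    assert 0.0 <= params["x"] <= 1.0 and score == -params["x"]


def test_refine_search_converges_on_deterministic_objective():
    # objective peaks at x = 42 in [0, 100]; 50 trials with interval
    # refinement must land close
    space = {"x": ("float", 0.0, 100.0)}
    params, _ = refine_search(lambda p: -abs(p["x"] - 42.0), space, n_trials=50, seed=3)
    assert abs(params["x"] - 42.0) < 3.0


def test_refine_search_int_and_log_params():
    space = {"n": ("int", 1, 100), "lr": ("logfloat", 1e-3, 0.3)}
    params, _ = refine_search(
        lambda p: -abs(p["n"] - 10) - abs(np.log10(p["lr"]) + 2), space,
        n_trials=40, seed=0,
    )
    assert isinstance(params["n"], int) and 1 <= params["n"] <= 100
    assert 1e-3 <= params["lr"] <= 0.3


def test_refine_search_empty_space_rejected():
    with pytest.raises(ValueError, match="empty"):
        refine_search(lambda p: 0.0, {}, n_trials=5)


def test_refine_search_deterministic():
    space = {"x": ("float", -1.0, 1.0)}
    r1 = refine_search(lambda p: p["x"], space, n_trials=20, seed=5)
    r2 = refine_search(lambda p: p["x"], space, n_trials=20, seed=5)
    assert r1 == r2


def test_tune_returns_params_in_bounds(small_attc):
    feats = [c for c in small_attc.columns if c not in ("sample_id", "response")]
    X = small_attc[feats].to_numpy()[:120]
    y = (small_attc["response"].to_numpy()[:120] > 0.5).astype(int)
    params, score = tune("random_forest", X, y, TaskSpec(0), n_trials=3, seed=0, cv=3)
    assert 50 <= params["n_estimators"] <= 2000
    assert 1 <= params["max_depth"] <= 25
    assert 0.0 <= score <= 1.0


def test_train_candidates_three_records(encoded_tfbs):
    X, y, _ = encoded_tfbs
    records = train_candidates(
        X, y, TaskSpec(0), n_trials=2, seed=0, cv=3, deep_forest_params=FAST_DF
    )
    assert [r.name for r in records] == [
        "random_forest", "xgboost", "weighted_deep_forest"
    ]
    assert not any(r.failed for r in records)
    for r in records:  # classification contract: probabilities available
        proba = r.model.predict_proba(X[:3])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


def test_select_best_single_candidate_trivial(rng):
    rec = CandidateRecord(name="only", params={}, model=_StubModel(rng.random_sample(20)))
    y = rng.randint(0, 2, 20)
    y[:2] = [0, 1]
    res = select_best([rec], np.zeros((20, 1)), y, TaskSpec(0))
    assert res.best_name == "only"


def test_select_best_accuracy_tie_broken_by_auc():
    y = np.array([1, 1, 0, 0])
    # both threshold to labels (1,0,0,0) -> accuracy 0.75; the scores
    # rank the classes perfectly for one model and at chance for the other
    sharp = _StubModel([0.9, 0.4, 0.2, 0.1])   # AUC 1.0
    blurry = _StubModel([0.9, 0.1, 0.4, 0.2])  # AUC 0.5
    assert (blurry.predict(None) == y).mean() == (sharp.predict(None) == y).mean()
    res = select_best(
        [CandidateRecord("blurry", {}, model=blurry),
         CandidateRecord("sharp", {}, model=sharp)],
        np.zeros((4, 1)), y, TaskSpec(0),
    )
    assert res.best_name == "sharp"
    assert res.records[0].validation_metrics["accuracy"] == pytest.approx(
        res.records[1].validation_metrics["accuracy"]
    )


def test_select_best_winner_not_dominated(encoded_tfbs):
    X, y, _ = encoded_tfbs
    idx = np.random.RandomState(0).permutation(len(y))
    X, y = X[idx], y[idx]
    records = train_candidates(
        X[:80], y[:80], TaskSpec(0), n_trials=2, seed=1, cv=3,
        deep_forest_params=FAST_DF,
    )
    res = select_best(records, X[80:], y[80:], TaskSpec(0))
    best = next(r for r in records if r.name == res.best_name)
    for r in records:
        if r is best or r.failed:
            continue
        dominated = all(
            r.validation_metrics[m] >= best.validation_metrics[m]
            for m in res.task.metric_priority
        ) and any(
            r.validation_metrics[m] > best.validation_metrics[m]
            for m in res.task.metric_priority
        )
        assert not dominated


def test_select_best_no_candidates_rejected():
    with pytest.raises(ValueError):
        select_best([CandidateRecord("x", {}, failed=True)], None, None, TaskSpec(0))


def test_predict_empty_test_set(rng):
    rec = CandidateRecord("m", {}, model=_StubModel([0.9]))
    from optimdase.select import SelectionResult
    res = SelectionResult(rec.model, "m", [rec], TaskSpec(0))
    out = predict(res, np.empty((0, 1)))
    assert out["labels"].size == 0


def test_optimdase_classification_end_to_end(encoded_tfbs):
    X, y, _ = encoded_tfbs
    model = OptimDase(flag=0, n_trials=2, cv=3, random_state=0,
                      deep_forest_params=FAST_DF).fit(X, y)
    assert model.best_name_ in {"random_forest", "xgboost", "weighted_deep_forest"}
    preds = model.predict(X)
    assert set(np.unique(preds)) <= {0, 1}
    assert (preds == y).mean() > 0.9  # near-training reproduction on separable data
    assert model.predict_proba(X).shape == (len(y), 2)


def test_optimdase_regression_in_range(small_attc):
    feats = [c for c in small_attc.columns if c not in ("sample_id", "response")]
    X = small_attc[feats].to_numpy()[:150]
    y = small_attc["response"].to_numpy()[:150]
    df_cfg = {k: v for k, v in FAST_DF.items() if k != "window"}
    model = OptimDase(flag=1, n_trials=2, cv=3, random_state=0,
                      deep_forest_params=df_cfg).fit(X, y)
    preds = model.predict(X)
    assert preds.min() >= -0.1 and preds.max() <= 1.1
    with pytest.raises(AttributeError):
        model.predict_proba(X)


def test_optimdase_deterministic(encoded_tfbs):
    X, y, _ = encoded_tfbs
    kw = dict(flag=0, n_trials=2, cv=3, random_state=7, deep_forest_params=FAST_DF)
    m1 = OptimDase(**kw).fit(X, y)
    m2 = OptimDase(**kw).fit(X, y)
    assert m1.best_name_ == m2.best_name_
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))
    for r1, r2 in zip(m1.result_.records, m2.result_.records):
        assert r1.validation_metrics == r2.validation_metrics


def test_predict_dimension_mismatch_named(encoded_tfbs):
    X, y, _ = encoded_tfbs
    model = OptimDase(flag=0, n_trials=1, cv=3, random_state=0,
                      deep_forest_params=FAST_DF).fit(X, y)
    with pytest.raises(ValueError, match="features"):
        predict(model.result_, X[:, :50])
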