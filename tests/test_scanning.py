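"""Weighted varied-granularity scanning and the cascade deep forest."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from optimdase.scanning import (
    WeightedDeepForestClassifier,
    WeightedDeepForestRegressor,
    fit_weighted_deep_forest,
    hadamard_weight,
    scan_transform,
    window_slices,
)


def test_window_slices_row_count_and_content():
    f, w = window_slices([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4], 2)
    assert f.shape == (3, 2)
    assert f.tolist() == [[1, 2], [2, 3], [3, 4]]
    assert w.tolist() == [[0.1, 0.2], [0.2, 0.3], [0.3, 0.4]]


def test_window_slices_full_width_single_row(rng):
    v = rng.normal(size=7)
    f, _ = window_slices(v, np.ones(7), 7)
    assert f.shape == (1, 7) and np.array_equal(f[0], v)


def test_window_slices_bad_m_rejected():
    with pytest.raises(ValueError):
        window_slices([1, 2], [1, 1], 3)
    with pytest.raises(ValueError, match="length"):
        window_slices([1, 2, 3], [1, 1], 2)


def test_hadamard_identity_zero_and_elementwise():
    f = np.array([[1.0, 2.0], [3.0, 4.0]])
    assert np.array_equal(hadamard_weight(f, np.ones_like(f)), f)
    assert hadamard_weight(f, np.zeros_like(f)).sum() == 0
    w = np.array([[0.5, 1.0], [1.0, 0.25]])
    assert hadamard_weight(f, w).tolist() == [[0.5, 2.0], [3.0, 1.0]]
    with pytest.raises(ValueError, match="shape"):
        hadamard_weight(f, np.ones((3, 2)))


def test_scan_transform_stump_trace():
    # depth-1 trees with known leaf distributions; trace 2 windows by hand
    Xw = np.array([[0.0], [1.0], [0.0], [1.0]])
    yw = np.array([0, 1, 0, 1])
    a = DecisionTreeClassifier(max_depth=1).fit(Xw, yw)
    b = DecisionTreeClassifier(max_depth=1).fit(Xw, yw)
    f_pre = np.array([[0.0], [1.0]])
    out = scan_transform(f_pre, a, b)
    assert out.shape == (8,)
    np.testing.assert_allclose(out, [1, 0, 0, 1, 1, 0, 0, 1])


def test_scan_transform_requires_fitted():
    with pytest.raises(Exception):
        scan_transform(np.zeros((2, 1)), DecisionTreeClassifier(), DecisionTreeClassifier())


@pytest.mark.parametrize("n,m", [(10, 3), (20, 5), (7, 7), (120, 3)])
def test_fout_shape_contract(n, m, rng):
    X = rng.normal(size=(40, n))
    y = (X[:, 0] > 0).astype(int)
    model = WeightedDeepForestClassifier(
        window=m, n_scanner_estimators=5, n_cascade_estimators=5,
        n_weight_estimators=10, max_layers=1, random_state=0,
    ).fit(X, y)
    F_out = model.transform(X)
    assert F_out.shape == (40, 4 * (n - m + 1))


def test_probability_rows_sum_to_one(encoded_tfbs):
    X, y, _ = encoded_tfbs
    model = WeightedDeepForestClassifier(
        window=3, n_scanner_estimators=10, n_cascade_estimators=10,
        n_weight_estimators=20, max_layers=1, random_state=0,
    ).fit(X, y)
    F_out = model.transform(X[:5])
    n_win = model.n_windows_
    f_a = F_out[:, : 2 * n_win].reshape(5, n_win, 2)
    f_b = F_out[:, 2 * n_win :].reshape(5, n_win, 2)
    np.testing.assert_allclose(f_a.sum(axis=2), 1.0, atol=1e-9)
    np.testing.assert_allclose(f_b.sum(axis=2), 1.0, atol=1e-9)


def test_identity_weights_reduce_to_unweighted_scanning(rng):
    # with all-equal weights the Hadamard step is a uniform rescaling of
    # every window, so the weighted window matrix is proportional to the
    # plain sliding-window matrix
    v = rng.normal(size=9)
    f, w = window_slices(v, np.full(9, 1.0), 4)
    assert np.array_equal(hadamard_weight(f, w), f)


def test_separable_data_perfect_training_accuracy(rng):
    X = np.vstack([rng.normal(-3, 0.3, size=(30, 4)), rng.normal(3, 0.3, size=(30, 4))])
    y = np.repeat([0, 1], 30)
    model = WeightedDeepForestClassifier(
        window=2, n_scanner_estimators=10, n_cascade_estimators=10,
        n_weight_estimators=10, max_layers=1, random_state=0,
    ).fit(X, y)
    assert (model.predict(X) == y).mean() == 1.0


def test_same_seed_identical_predictions(encoded_tfbs):
    X, y, _ = encoded_tfbs
    kw = dict(window=3, n_scanner_estimators=8, n_cascade_estimators=8,
              n_weight_estimators=10, max_layers=2, random_state=42)
    p1 = WeightedDeepForestClassifier(**kw).fit(X, y).predict_proba(X)
    p2 = WeightedDeepForestClassifier(**kw).fit(X, y).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


def test_single_class_rejected(rng):
    X = rng.normal(size=(20, 5))
    with pytest.raises(ValueError, match="single class"):
        WeightedDeepForestClassifier(window=2).fit(X, np.zeros(20, dtype=int))


def test_feature_count_mismatch_at_predict(encoded_tfbs):
    X, y, _ = encoded_tfbs
    model = WeightedDeepForestClassifier(
        window=3, n_scanner_estimators=5, n_cascade_estimators=5,
        n_weight_estimators=10, max_layers=1, random_state=0,
    ).fit(X, y)
    with pytest.raises(ValueError, match="features"):
        model.predict(X[:, :100])


def test_regressor_predicts_in_response_range(small_attc):
    feats = [c for c in small_attc.columns if c not in ("sample_id", "response")]
    X = small_attc[feats].to_numpy()
    y = small_attc["response"].to_numpy()
    model = WeightedDeepForestRegressor(
        n_scanner_estimators=8, n_cascade_estimators=8,
        n_weight_estimators=10, max_layers=1, random_state=0,
    ).fit(X, y)
    preds = model.predict(X)
    assert preds.min() >= y.min() - 0.1 and preds.max() <= y.max() + 0.1
    # regressor representation: one value per window per scanner
    assert model.transform(X[:3]).shape[1] == 2 * model.n_windows_


def test_fit_weighted_deep_forest_dispatch(small_attc, encoded_tfbs):
    X, y, _ = encoded_tfbs
    cfg = dict(window=3, n_scanner_estimators=5, n_cascade_estimators=5,
               n_weight_estimators=10, max_layers=1)
    idx = np.r_[0:20, 100:120]  # both classes represented
    clf = fit_weighted_deep_forest(X[idx], y[idx], cfg, seed=0)
    assert isinstance(clf, WeightedDeepForestClassifier)
    feats = [c for c in small_attc.columns if c not in ("sample_id", "response")]
    reg = fit_weighted_deep_forest(
        small_attc[feats].to_numpy()[:60], small_attc["response"].to_numpy()[:60],
        dict(n_scanner_estimators=5, n_cascade_estimators=5,
             n_weight_estimators=10, max_layers=1), seed=0,
    )
    assert isinstance(reg, WeightedDeepForestRegressor)
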