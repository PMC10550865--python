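"""sPLS-DA core: sparsity operator, NIPALS fit, prediction, error rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bccstrat import dummy_code, error_rate, fit_splsda, predict, soft_threshold
from bccstrat.splsda import SplsdaError, transform


def test_dummy_code_basic():
    Y, classes = dummy_code(["success", "failure", "success"])
    assert list(classes) == ["success", "failure"]
    np.testing.assert_array_equal(Y, [[1, 0], [0, 1], [1, 0]])
    assert Y.sum(axis=0).tolist() == [2, 1]  # column sums = class counts
    Y3, c3 = dummy_code(["CE", "LAA", "UND", "CE"])
    assert Y3.shape == (4, 3)
    with pytest.raises(SplsdaError):
        dummy_code(["only"] * 5)


def test_soft_threshold_hand_example():
    out = soft_threshold(np.array([3.0, 1.0, -2.0]), keep=1)
    np.testing.assert_allclose(out, [1.0, 0.0, 0.0])  # shrink by lambda=2, renormalize


def test_soft_threshold_keep_all_preserves_direction(rng):
    v = rng.normal(size=10)
    out = soft_threshold(v, keep=10)
    np.testing.assert_allclose(out, v / np.linalg.norm(v))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    v=st.lists(st.floats(-100, 100).filter(lambda x: abs(x) > 1e-6),
               min_size=2, max_size=20),
    keep_frac=st.floats(0.01, 1.0),
)
def test_soft_threshold_sign_symmetry_and_exact_support(v, keep_frac):
    v = np.array(v)
    keep = max(1, int(np.ceil(keep_frac * len(v))))
    out = soft_threshold(v, keep)
    assert np.count_nonzero(out) == keep
    assert np.linalg.norm(out) == pytest.approx(1.0)
    np.testing.assert_allclose(soft_threshold(-v, keep), -out, atol=1e-12)


def test_soft_threshold_tie_break_first_index():
    out = soft_threshold(np.array([2.0, 2.0, 1.0]), keep=1)
    assert out[0] != 0 and out[1] == 0  # stable order prefers the first


def test_soft_threshold_range_errors():
    with pytest.raises(SplsdaError):
        soft_threshold(np.ones(3), 0)
    with pytest.raises(SplsdaError):
        soft_threshold(np.ones(3), 4)


def test_first_weight_equals_dominant_singular_direction():
    from bccstrat.experiments import splsda_svd_deviation

    assert splsda_svd_deviation(seed=0, n_instances=5) < 1e-6


def test_fit_is_deterministic_with_duplicated_features(rng):
    X = rng.normal(size=(80, 6))
    X = np.hstack([X, X[:, :2]])  # exact duplicates
    y = np.where(rng.random(80) < 0.5, "a", "b")
    m1 = fit_splsda(X, y, ncomp=2, keepX=[3, 3])
    m2 = fit_splsda(X, y, ncomp=2, keepX=[3, 3])
    np.testing.assert_array_equal(m1.weights, m2.weights)
    # sign convention: top entry of each weight vector is positive
    for h in range(2):
        assert m1.weights[np.argmax(np.abs(m1.weights[:, h])), h] > 0


def test_planted_informative_variables_selected(rng):
    n, p = 200, 20
    X = rng.normal(size=(n, p))
    y = np.where(rng.random(n) < 0.5, "a", "b")
    X[y == "a", 3] += 3.0
    X[y == "a", 11] -= 3.0
    model = fit_splsda(X, y, ncomp=1, keepX=[2])
    assert set(np.flatnonzero(model.weights[:, 0])) == {3, 11}


def test_scores_orthogonal_across_components(rng):
    X = rng.normal(size=(100, 15))
    y = np.where(rng.random(100) < 0.5, "a", "b")
    model = fit_splsda(X, y, ncomp=2, keepX=[10, 10])
    t1, t2 = model.x_scores[:, 0], model.x_scores[:, 1]
    assert abs(t1 @ t2) < 1e-8 * np.linalg.norm(t1) * np.linalg.norm(t2)


def test_dense_fit_agrees_with_reference_plsda(rng):
    """keepX = all: predictions match sklearn's dense PLS regression argmax."""
    from sklearn.cross_decomposition import PLSRegression

    n, p = 200, 12
    X = rng.normal(size=(n, p))
    y = np.where(rng.random(n) < 0.5, "a", "b")
    X[y == "a", 0] += 1.5
    X[y == "a", 5] += 1.0
    model = fit_splsda(X, y, ncomp=2, keepX=[p, p])
    mine = predict(model, X)

    Y, classes = dummy_code(y)
    ref = PLSRegression(n_components=2, scale=True).fit(X, Y)
    ref_pred = classes[np.argmax(ref.predict(X), axis=1)]
    assert np.mean(mine == ref_pred) >= 0.95


def test_predict_interior_point_and_midpoint_tie(rng):
    X = np.vstack([rng.normal(-3, 0.5, (40, 4)), rng.normal(3, 0.5, (40, 4))])
    y = np.array(["lo"] * 40 + ["hi"] * 40)
    model = fit_splsda(X, y, ncomp=1, keepX=[4])
    assert predict(model, np.full((1, 4), -3.0))[0] == "lo"
    assert predict(model, np.full((1, 4), 3.0))[0] == "hi"
    # exact midpoint: deterministic tie-break to the first class label
    mid = model.train_means[None, :]
    assert predict(model, mid)[0] == model.classes[0]


def test_predict_dimension_mismatch_raises(rng):
    X = rng.normal(size=(50, 5))
    y = np.where(rng.random(50) < 0.5, "a", "b")
    model = fit_splsda(X, y, ncomp=1)
    with pytest.raises(SplsdaError):
        predict(model, rng.normal(size=(3, 4)))


def test_distance_rules_agree_on_well_separated_classes(rng):
    X = np.vstack([rng.normal(-2, 1, (60, 6)), rng.normal(2, 1, (60, 6))])
    y = np.array(["a"] * 60 + ["b"] * 60)
    model = fit_splsda(X, y, ncomp=2)
    for rule in ("max_dist", "centroid", "mahalanobis"):
        assert np.mean(predict(model, X, distance_rule=rule) == y) > 0.95


def test_error_rate_definition_and_relabel_invariance():
    assert error_rate(["a", "a"], ["a", "a"]) == 0.0
    assert error_rate(["a", "a"], ["b", "b"]) == 1.0
    pred = np.array(["s"] * 57 + ["f"] * 43)
    truth = np.array(["s"] * 100)
    assert error_rate(pred, truth) == pytest.approx(0.43)
    relabel = {"s": "x", "f": "y"}
    assert error_rate([relabel[p] for p in pred], [relabel[t] for t in truth]) == \
        pytest.approx(0.43)
    with pytest.raises(SplsdaError):
        error_rate([], [])


def test_keepx_out_of_range_raises(rng):
    X = rng.normal(size=(30, 5))
    y = np.where(rng.random(30) < 0.5, "a", "b")
    with pytest.raises(SplsdaError):
        fit_splsda(X, y, ncomp=1, keepX=[6])


def test_transform_of_training_data_reproduces_scores(rng):
    X = rng.normal(size=(60, 8))
    y = np.where(rng.random(60) < 0.5, "a", "b")
    model = fit_splsda(X, y, ncomp=2, keepX=[4, 4])
    np.testing.assert_allclose(transform(model, X), model.x_scores, atol=1e-10)
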