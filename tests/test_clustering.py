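"""Collinearity clustering: Spearman distance, tree cuts, Rand index, k selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bccstrat import (
    GeneratorConfig,
    cluster_variables,
    correlation_distance,
    generate_cohort,
    make_representatives,
    rand_index,
    select_k,
)
from bccstrat.clustering import ClusterError
from bccstrat.simulate import bcc_columns


def test_perfectly_correlated_pair_distance_zero(rng):
    x = rng.normal(size=200)
    X = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=200)})
    D = correlation_distance(X)
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


def test_independent_pair_distance_near_one(rng):
    X = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
    D = correlation_distance(X)
    assert D[0, 1] == pytest.approx(1.0, abs=0.08)  # null Spearman SE ~ 1/sqrt(n)


def test_constant_column_gets_distance_one_with_warning(rng):
    X = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
    with pytest.warns(UserWarning, match="constant"):
        D = correlation_distance(X)
    assert D[0, 1] == 1.0


def test_trivial_cuts():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(60, 6)))
    D = correlation_distance(X)
    assert len(set(cluster_variables(D, 6))) == 6
    assert len(set(cluster_variables(D, 1))) == 1
    with pytest.raises(ClusterError):
        cluster_variables(D, 7)


def test_planted_blocks_recovered_at_true_k(default_cohort):
    cfg, cohort, truth = default_cohort
    X = cohort[bcc_columns(cfg.n_bcc)]
    labels = cluster_variables(correlation_distance(X), 58)
    _, ari = rand_index(labels, truth.assignment_vector())
    assert ari == pytest.approx(1.0)


def test_rand_index_identities():
    assert rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == (1.0, 1.0)
    rand, _ = rand_index([1, 1, 2, 2], [1, 2, 1, 2])  # {ab|cd} vs {ac|bd}
    assert rand == pytest.approx(2 / 6)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    labels1=st.lists(st.integers(0, 4), min_size=2, max_size=30),
    labels2_seed=st.integers(0, 2**16),
)
def test_rand_index_symmetry_and_sklearn_oracle(labels1, labels2_seed):
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(labels2_seed)
    labels2 = rng.integers(0, 4, len(labels1)).tolist()
    r12, a12 = rand_index(labels1, labels2)
    r21, a21 = rand_index(labels2, labels1)
    assert r12 == pytest.approx(r21) and a12 == pytest.approx(a21)
    assert 0.0 <= r12 <= 1.0 and a12 <= 1.0
    assert a12 == pytest.approx(adjusted_rand_score(labels1, labels2))


def test_clustering_invariant_to_order_and_monotone_transform(small_planted):
    cfg, cohort, truth, _ = small_planted
    X = cohort[bcc_columns(cfg.n_bcc)]
    base = cluster_variables(correlation_distance(X), cfg.n_clusters)
    # monotone transform leaves Spearman distances unchanged
    mono = cluster_variables(correlation_distance(np.exp(X / 2)), cfg.n_clusters)
    assert rand_index(base, mono)[1] == pytest.approx(1.0)
    # variable order permutation permutes labels consistently
    perm = np.random.default_rng(0).permutation(cfg.n_bcc)
    shuffled = X.iloc[:, perm]
    permuted = cluster_variables(correlation_distance(shuffled), cfg.n_clusters)
    assert rand_index(base[perm], permuted)[1] == pytest.approx(1.0)


def test_select_k_single_block_chooses_one():
    cfg = GeneratorConfig(
        seed=2, n_female=80, n_male=80, n_bcc=6, n_clusters=1,
        rho_within=0.95, rho_between=0.0, sex_shift_vars={},
        informative_clusters={"shared": {}}, etiology_clusters={"shared": {}},
    )
    cohort, _ = generate_cohort(cfg)
    model = select_k(cohort[bcc_columns(6)], cohort["sex"].to_numpy(), [1, 2, 3])
    assert model.k == 1
    assert model.concordance == pytest.approx(1.0)


def test_select_k_recovers_planted_58(default_cohort):
    cfg, cohort, truth = default_cohort
    model = select_k(cohort[bcc_columns(cfg.n_bcc)], cohort["sex"].to_numpy(),
                     range(40, 71))
    assert model.k == 58
    fitted = np.array([model.partition[v] for v in bcc_columns(cfg.n_bcc)])
    assert rand_index(fitted, truth.assignment_vector())[1] >= 0.95
    assert 0.0 <= model.concordance <= 1.0


def test_representatives_singleton_and_symmetric_members(rng):
    x = rng.normal(2.0, 3.0, 300)
    X = pd.DataFrame({"a": x, "b": 5 * x - 1, "c": rng.normal(size=300)})
    reps, means, sds = make_representatives(X, {"a": 1, "b": 1, "c": 2})
    # singleton passes through z-scored
    np.testing.assert_allclose(
        reps["cluster_02"], (X["c"] - means["c"]) / sds["c"]
    )
    # perfectly correlated members: representative correlates 1.0 with each
    assert np.corrcoef(reps["cluster_01"], X["a"])[0, 1] == pytest.approx(1.0)
    assert np.corrcoef(reps["cluster_01"], X["b"])[0, 1] == pytest.approx(1.0)


def test_representative_beats_members_at_tracking_latent_factor(rng):
    # two members sharing a latent factor at rho 0.9
    n = 2000
    f = rng.normal(size=n)
    x1 = np.sqrt(0.9) * f + np.sqrt(0.1) * rng.normal(size=n)
    x2 = np.sqrt(0.9) * f + np.sqrt(0.1) * rng.normal(size=n)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    reps, _, _ = make_representatives(X, {"x1": 1, "x2": 1})
    r_rep = np.corrcoef(reps["cluster_01"], f)[0, 1]
    assert r_rep > np.corrcoef(x1, f)[0, 1]
    assert r_rep > np.corrcoef(x2, f)[0, 1]


def test_representatives_with_training_constants_do_not_refit(rng):
    X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
    part = {"a": 1, "b": 1, "c": 2}
    _, means, sds = make_representatives(X, part)
    Xnew = X + 100.0  # wildly shifted "test" data
    reps_new, _, _ = make_representatives(Xnew, part, means, sds)
    assert reps_new.to_numpy().mean() > 10  # z-scored with training constants


def test_zero_sd_member_excluded_with_warning(rng):
    X = pd.DataFrame({"a": rng.normal(size=40), "b": np.full(40, 7.0)})
    with pytest.warns(UserWarning, match="zero-SD"):
        reps, _, _ = make_representatives(X, {"a": 1, "b": 1})
    assert np.isfinite(reps.to_numpy()).all()
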