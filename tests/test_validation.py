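"""Repeated CV, selection frequencies, stable sets, Welch comparisons."""

import numpy as np
import pytest
from scipy import stats

from bccstrat import repeated_cv, stratified_comparison, welch_t
from bccstrat.simulate import bcc_columns
from bccstrat.validation import ValidationError


def test_welch_identical_sample_twice_gives_t_zero():
    e = np.array([0.41, 0.43, 0.45, 0.40, 0.42])
    t, df, p = welch_t(e, e)
    assert t == 0.0 and p == 1.0


def test_welch_matches_scipy_and_textbook_df(rng):
    e1 = rng.normal(0.41, 0.02, 100)
    e2 = rng.normal(0.43, 0.02, 100)
    t, df, p = welch_t(e1, e2)
    ref = stats.ttest_ind(e1, e2, equal_var=False)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
    v1, v2 = e1.var(ddof=1), e2.var(ddof=1)
    df_ref = (v1 / 100 + v2 / 100) ** 2 / (
        (v1 / 100) ** 2 / 99 + (v2 / 100) ** 2 / 99
    )
    assert df == pytest.approx(df_ref)
    # swap symmetry
    t2, df2, p2 = welch_t(e2, e1)
    assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)


def test_welch_zero_variance_both_raises():
    with pytest.raises(ValidationError):
        welch_t([0.4, 0.4], [0.5, 0.5])


def test_repeated_cv_structure_and_determinism(small_planted):
    cfg, cohort, truth, partition = small_planted
    X = cohort[bcc_columns(cfg.n_bcc)]
    y = cohort["recanalization"].to_numpy()
    res = repeated_cv(X, y, partition=partition, K=3, R=4, seed=5,
                      keepX_grid=(2, 4), inner_folds=2)
    assert len(res.error_rates) == 4
    assert 0.0 <= res.mean_error <= 1.0
    assert all(0.0 <= f <= 1.0 for f in res.selection_frequency.values())
    assert res.stable_set == {
        c for c, f in res.selection_frequency.items() if f > res.threshold
    }
    res2 = repeated_cv(X, y, partition=partition, K=3, R=4, seed=5,
                       keepX_grid=(2, 4), inner_folds=2)
    np.testing.assert_array_equal(res.error_rates, res2.error_rates)
    assert res.selection_frequency == res2.selection_frequency


def test_repeated_cv_recovers_strong_planted_clusters(small_planted):
    cfg, cohort, truth, partition = small_planted
    X = cohort[bcc_columns(cfg.n_bcc)]
    y = cohort["recanalization"].to_numpy()
    res = repeated_cv(X, y, partition=partition, K=5, R=8, seed=1,
                      keepX_grid=(2, 4, 6), inner_folds=3)
    planted = {f"cluster_{c + 1:02d}" for c in truth.informative_clusters["shared"]}
    assert len(res.stable_set & planted) >= 2  # 3 planted, strong effects
    assert res.mean_error < 0.40


def test_stable_set_shrinks_as_threshold_rises(small_planted):
    cfg, cohort, truth, partition = small_planted
    X = cohort[bcc_columns(cfg.n_bcc)]
    y = cohort["recanalization"].to_numpy()
    res = repeated_cv(X, y, partition=partition, K=3, R=3, seed=2,
                      keepX_grid=(2, 4), inner_folds=2, threshold=0.5)
    higher = {c for c, f in res.selection_frequency.items() if f > 0.95}
    assert higher <= res.stable_set


def test_class_smaller_than_k_raises(rng):
    X = rng.normal(size=(20, 4))
    y = np.array(["a"] * 17 + ["b"] * 3)
    with pytest.raises(ValidationError):
        repeated_cv(X, y, K=5, R=1)


def test_stratified_comparison_structure(small_planted):
    cfg, cohort, truth, partition = small_planted
    comp = stratified_comparison(
        cohort[bcc_columns(cfg.n_bcc)],
        cohort["recanalization"].to_numpy(),
        cohort["sex"].to_numpy(),
        partition=partition,
        K=3, R=3, seed=4, keepX_grid=(2, 4), inner_folds=2,
    )
    assert set(comp.results) == {"pooled", "F", "M"}
    assert set(comp.welch) == {"F_vs_pooled", "M_vs_pooled", "F_vs_M"}
    for t, df, p in comp.welch.values():
        assert 0.0 <= p <= 1.0 and df > 0


def test_equal_effects_in_both_sexes_leave_little_stratification_gain():
    """With identical shared effects, pooled and stratified errors are close."""
    from bccstrat import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(
        seed=29, n_female=150, n_male=150, sex_shift_vars={},
        informative_clusters={"shared": {5: 1.0, 25: -1.0, 45: 1.0}},
        etiology_clusters={"shared": {}},
    )
    cohort, truth = generate_cohort(cfg)
    partition = {v: c + 1 for v, c in truth.cluster_assignment.items()}
    comp = stratified_comparison(
        cohort[bcc_columns(cfg.n_bcc)],
        cohort["recanalization"].to_numpy(),
        cohort["sex"].to_numpy(),
        partition=partition, K=5, R=10, seed=3,
    )
    pooled = comp.results["pooled"].mean_error
    strat = 0.5 * (comp.results["F"].mean_error + comp.results["M"].mean_error)
    assert abs(pooled - strat) < 0.06


def test_missing_sex_raises(small_planted):
    cfg, cohort, truth, partition = small_planted
    with pytest.raises(ValidationError):
        stratified_comparison(
            cohort[bcc_columns(cfg.n_bcc)],
            cohort["recanalization"].to_numpy(),
            np.array(["F"] * len(cohort)),
            partition=partition, K=3, R=2,
        )
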