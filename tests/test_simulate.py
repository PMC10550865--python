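"""Generator: dimensions, determinism, planted correlation/shift structure."""

import numpy as np
import pandas as pd
import pytest

from bccstrat import ConfigError, GeneratorConfig, generate_cohort, generate_reports
from bccstrat.simulate import bcc_columns, cluster_means


def test_default_cohort_dimensions(default_cohort):
    cfg, cohort, truth = default_cohort
    assert len(cohort) == 333
    assert (cohort["sex"] == "F").sum() == 143
    assert (cohort["sex"] == "M").sum() == 190
    assert len([c for c in cohort.columns if c.startswith("bcc_")]) == 71
    assert sorted(set(truth.cluster_assignment.values())) == list(range(58))
    assert truth.cluster_sizes.count(1) == 45 and truth.cluster_sizes.count(2) == 13


def test_same_seed_reproduces_cohort_and_reports():
    cfg = GeneratorConfig(seed=3, n_female=40, n_male=40, none_rate=0.1, conflict_rate=0.1)
    c1, _ = generate_cohort(cfg)
    c2, _ = generate_cohort(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    r1, s1 = generate_reports(c1, cfg)
    r2, s2 = generate_reports(c2, cfg)
    assert r1 == r2 and s1 == s2


def test_within_block_correlation_matches_target(default_cohort):
    # Fisher-z SE at n=333 is ~0.055; +-0.08 covers the sampling noise
    cfg, cohort, truth = default_cohort
    X = cohort[bcc_columns(cfg.n_bcc)].to_numpy()
    assign = truth.assignment_vector()
    # restrict to unshifted variables so pooled correlations are clean
    shifted = set(truth.sex_shift_vars)
    for c, size in enumerate(truth.cluster_sizes):
        idx = np.flatnonzero(assign == c)
        if size == 2 and not (set(idx) & shifted):
            r = np.corrcoef(X[:, idx[0]], X[:, idx[1]])[0, 1]
            assert abs(r - cfg.rho_within) < 0.08


def test_sex_shift_recovered_in_marginal_means(default_cohort):
    cfg, cohort, truth = default_cohort
    f = cohort["sex"] == "F"
    se = np.sqrt(1 / f.sum() + 1 / (~f).sum())
    devs = []
    for v, delta in truth.sex_shift_vars.items():
        col = bcc_columns(cfg.n_bcc)[v]
        diff = cohort.loc[f, col].mean() - cohort.loc[~f, col].mean()
        devs.append(abs(diff - delta) / se)
    # per-variable 3-SE bound holds family-wise up to one chance excursion
    assert max(devs) < 4.0
    assert sum(d < 3.0 for d in devs) >= len(devs) - 1


def test_null_signal_gives_chance_level_outcome_structure():
    cfg = GeneratorConfig(
        seed=11,
        n_female=400,
        n_male=400,
        sex_shift_vars={},
        informative_clusters={"shared": {}},
        etiology_clusters={"shared": {}},
    )
    cohort, truth = generate_cohort(cfg)
    y = (cohort["recanalization"] == "success").to_numpy(float)
    # intercept 0 -> success probability one half
    assert abs(y.mean() - 0.5) < 3 * 0.5 / np.sqrt(800)
    X = cohort[bcc_columns(cfg.n_bcc)].to_numpy()
    reps = cluster_means(X, truth.assignment_vector())
    cors = [abs(np.corrcoef(reps[:, c], y)[0, 1]) for c in range(cfg.n_clusters)]
    assert max(cors) < 0.15  # pure noise at n=800


def test_missingness_respects_configured_rate():
    cfg = GeneratorConfig(seed=5, missing_rate=0.1)
    cohort, _ = generate_cohort(cfg)
    frac = cohort[bcc_columns(cfg.n_bcc)].isna().mean()
    assert (frac <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / len(cohort))).all()


def test_lognormal_marginals_are_positive():
    cfg = GeneratorConfig(seed=5, marginal="lognormal", sex_shift_vars={})
    cohort, _ = generate_cohort(cfg)
    assert (cohort[bcc_columns(cfg.n_bcc)] > 0).all().all()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_clusters": 80},  # more clusters than variables
        {"rho_within": 0.2, "rho_between": 0.5},  # inverted correlations
        {"missing_rate": 1.0},
        {"covariate_prevalences": {"hypertension": 1.5}},
        {"informative_clusters": {"shared": {0: 1.0}, "female_only": {0: 1.0}}},
        {"sex_shift_vars": {99: 0.5}},
        {"none_rate": 0.8, "conflict_rate": 0.8},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        GeneratorConfig(seed=0, **kwargs)


def test_clean_reports_carry_exactly_one_grade_token(default_cohort):
    import re

    cfg, cohort, _ = default_cohort  # defaults: no noise, no triage fractions
    reports, statuses = generate_reports(cohort, cfg)
    assert set(statuses.values()) == {"clean"}
    pat = re.compile(r"[em]?TICI", re.IGNORECASE)
    for rec in reports:
        assert len(pat.findall(rec["text"])) == 1


def test_conflict_fraction_matches_configuration():
    cfg = GeneratorConfig(seed=21, n_female=100, n_male=100, conflict_rate=0.1)
    cohort, _ = generate_cohort(cfg)
    reports, statuses = generate_reports(cohort, cfg)
    n_conflict = sum(1 for s in statuses.values() if s == "conflict")
    assert abs(n_conflict - 20) <= 3 * np.sqrt(200 * 0.1 * 0.9)
    # direct scan: conflicting reports really contain two distinct grades
    from bccstrat import extract_tici

    for rec in reports:
        if statuses[rec["patient_id"]] == "conflict":
            assert len(extract_tici(rec["text"]).grades_found) == 2
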