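"""Calibration and recovery experiments on synthetic cohorts.

These are the package's evidence that each stage behaves as designed:
closed-form contingency checks on the published baseline table, oracle
equivalences (sPLS-DA vs dense SVD, IRLS vs a reference GLM), planted-truth
recovery for the clustering and stability-selection stages, and the
sex-stratification power experiment.  Both the test suite and
``scripts/acceptance.py`` run these functions.
"""

from __future__ import annotations

import numpy as np

from .clustering import rand_index, select_k
from .config import GeneratorConfig
from .screen import bh_adjust, chi_square_2x2
from .simulate import generate_cohort, generate_reports, bcc_columns
from .splsda import dummy_code, fit_splsda
from .tici import extract_corpus
from .validation import repeated_cv, stratified_comparison, welch_t

# Success-by-sex counts from the published baseline table:
# women 73 success / 70 failure, men 88 success / 102 failure.
SUCCESS_BY_SEX = (73, 70, 88, 102)


def _child_seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), tag])
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def success_by_sex_chi2() -> tuple[float, float]:
    """Pearson chi-square on the published success-by-sex 2x2 table."""
    stat, p, _ = chi_square_2x2(*SUCCESS_BY_SEX)
    return stat, p


def table1_percentages() -> dict[str, float]:
    """Recompute baseline-table percentages from their printed counts."""
    return {
        "female_success_pct": 100.0 * 73 / 143,
        "ce_in_female_success_pct": 100.0 * 34 / 73,
        "laa_in_female_success_pct": 100.0 * 19 / 73,
    }


def splsda_svd_deviation(seed: int = 0, n_instances: int = 20, n: int = 100,
                         p: int = 20) -> float:
    """Max deviation of component-1 weights from the dense SVD oracle.

    With keepX = all variables the first sPLS-DA weight vector must equal
    the dominant left singular vector of the centered X'Y cross-covariance
    (up to sign).  Returns the worst absolute elementwise deviation over
    random instances.
    """
    worst = 0.0
    for s in _child_seeds(seed, n_instances, 11):
        rng = np.random.default_rng(s)
        X = rng.standard_normal((n, p))
        y = np.where(rng.random(n) < 0.5, "a", "b")
        if np.unique(y).size < 2:  # pragma: no cover - vanishing probability
            y[0] = "a" if y[0] == "b" else "b"
        Xc = X - X.mean(axis=0)
        Y, _ = dummy_code(y)
        Yc = Y - Y.mean(axis=0)
        U, _, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        u1 = U[:, 0]
        model = fit_splsda(Xc, y, ncomp=1, keepX=[p], standardize=False)
        w = model.weights[:, 0]
        if np.dot(w, u1) < 0:
            u1 = -u1
        worst = max(worst, float(np.max(np.abs(w - u1))))
    return worst


def irls_oracle_deviation(seed: int = 0, n_datasets: int = 20) -> dict[str, float]:
    """Compare the in-house IRLS logistic fit with a reference GLM.

    Returns the worst coefficient deviation over random small datasets and
    the worst deviation of a single-binary-covariate beta from the closed
    form ln(ad/bc) on random 2x2 tables.
    """
    import statsmodels.api as sm  # reference implementation, oracle only

    from .adjusted import logistic_irls

    worst_coef = 0.0
    for s in _child_seeds(seed, n_datasets, 23):
        rng = np.random.default_rng(s)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        beta_true = rng.uniform(-1, 1, 4)
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        if y.sum() in (0, n):  # pragma: no cover - vanishing probability
            y[0] = 1 - y[0]
        beta, _ = logistic_irls(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        worst_coef = max(worst_coef, float(np.max(np.abs(beta - ref.params))))

    worst_or = 0.0
    for s in _child_seeds(seed, n_datasets, 29):
        rng = np.random.default_rng(s)
        a, b, c, d = rng.integers(5, 60, size=4)
        x = np.repeat([1, 1, 0, 0], [a, b, c, d]).astype(float)
        y = np.repeat([1, 0, 1, 0], [a, b, c, d]).astype(float)
        beta, _ = logistic_irls(np.column_stack([np.ones_like(x), x]), y)
        worst_or = max(worst_or, abs(beta[1] - np.log(a * d / (b * c))))
    return {"max_coef_dev": worst_coef, "max_logodds_dev": float(worst_or)}


def clustering_recovery(seed: int = 0, n_seeds: int = 20,
                        k_grid=range(40, 71)) -> dict[str, float]:
    """Planted-block recovery of the clustering stage.

    Generates default cohorts (71 BCCs in 58 blocks, within-block rho 0.9),
    runs sex-concordance model selection over the k grid, and reports how
    often k = 58 is chosen and how often the final partition matches the
    planted one at ARI >= 0.95.
    """
    k_hits = 0
    ari_hits = 0
    aris = []
    for s in _child_seeds(seed, n_seeds, 37):
        cfg = GeneratorConfig(seed=s)
        cohort, truth = generate_cohort(cfg)
        X = cohort[bcc_columns(cfg.n_bcc)]
        model = select_k(X, cohort["sex"].to_numpy(), k_grid)
        planted = truth.assignment_vector()
        fitted = np.array([model.partition[v] for v in X.columns])
        _, ari = rand_index(planted, fitted)
        aris.append(ari)
        k_hits += int(model.k == 58)
        ari_hits += int(ari >= 0.95)
    return {
        "k58_fraction": k_hits / n_seeds,
        "ari_recovery_fraction": ari_hits / n_seeds,
        "mean_ari": float(np.mean(aris)),
        "n_seeds": n_seeds,
    }


PLANTED_STABILITY_CLUSTERS = (5, 15, 25, 35, 45)


def _stability_config(seed: int, effect: float) -> GeneratorConfig:
    # n = 300 balanced, signal (if any) in five shared clusters, no sex shifts
    informative = (
        {"shared": {c: effect for c in PLANTED_STABILITY_CLUSTERS}}
        if effect != 0
        else {"shared": {}}
    )
    return GeneratorConfig(
        seed=seed,
        n_female=150,
        n_male=150,
        sex_shift_vars={},
        informative_clusters=informative,
        etiology_clusters={"shared": {}},
    )


def stability_recovery(seed: int = 0, n_replicates: int = 20, R: int = 25,
                       K: int = 5, effect: float = 0.8) -> dict[str, float]:
    """Stability-selection recovery of five planted informative clusters.

    Per replicate: generate n=300 with per-cluster log-odds ``effect`` on the
    five planted clusters, run K-fold CV repeated R times, and check whether
    at least 4 of the 5 planted clusters exceed the 0.9 selection-frequency
    threshold.  Returns the success fraction and mean CV error.
    """
    planted = {f"cluster_{c + 1:02d}" for c in PLANTED_STABILITY_CLUSTERS}
    hits = 0
    errors = []
    for s in _child_seeds(seed, n_replicates, 41):
        cfg = _stability_config(s, effect)
        cohort, truth = generate_cohort(cfg)
        part = {v: c + 1 for v, c in truth.cluster_assignment.items()}
        res = repeated_cv(
            cohort[bcc_columns(cfg.n_bcc)],
            cohort["recanalization"].to_numpy(),
            partition=part,
            K=K,
            R=R,
            seed=s,
        )
        hits += int(len(res.stable_set & planted) >= 4)
        errors.append(res.mean_error)
    return {
        "recovery_fraction": hits / n_replicates,
        "mean_cv_error": float(np.mean(errors)),
        "n_replicates": n_replicates,
    }


def stability_null(seed: int = 0, n_replicates: int = 20, R: int = 25,
                   K: int = 5) -> dict[str, float]:
    """Null calibration: with zero planted effects, the stable set is empty.

    Returns the fraction of replicates with no cluster above the 0.9
    threshold, and the mean CV error (which should sit near the
    majority-class rate).
    """
    clean = 0
    errors = []
    max_freqs = []
    for s in _child_seeds(seed, n_replicates, 43):
        cfg = _stability_config(s, 0.0)
        cohort, truth = generate_cohort(cfg)
        part = {v: c + 1 for v, c in truth.cluster_assignment.items()}
        y = cohort["recanalization"].to_numpy()
        res = repeated_cv(
            cohort[bcc_columns(cfg.n_bcc)], y, partition=part, K=K, R=R, seed=s
        )
        clean += int(len(res.stable_set) == 0)
        errors.append(res.mean_error)
        max_freqs.append(max(res.selection_frequency.values(), default=0.0))
    return {
        "clean_fraction": clean / n_replicates,
        "mean_cv_error": float(np.mean(errors)),
        "mean_max_frequency": float(np.mean(max_freqs)),
        "n_replicates": n_replicates,
    }


def stratification_power(seed: int = 0, n_seeds: int = 20, R: int = 25,
                         K: int = 5, effect: float = 1.0,
                         n_clusters_informative: int = 5) -> dict[str, float]:
    """Female-only planted effects: the female model should beat the pooled.

    Per seed: generate the default-size cohort (143 F / 190 M) with
    ``effect`` log-odds on five female-only clusters and nothing else, run
    the pooled/female/male comparison, and check that the female error is
    below the pooled error with Welch p < 0.05.
    """
    informative = {
        "shared": {},
        "female_only": {c: effect for c in PLANTED_STABILITY_CLUSTERS[:n_clusters_informative]},
        "male_only": {},
    }
    hits = 0
    f_errors, p_errors = [], []
    for s in _child_seeds(seed, n_seeds, 47):
        cfg = GeneratorConfig(
            seed=s,
            sex_shift_vars={},
            informative_clusters=informative,
            etiology_clusters={"shared": {}},
        )
        cohort, truth = generate_cohort(cfg)
        part = {v: c + 1 for v, c in truth.cluster_assignment.items()}
        comp = stratified_comparison(
            cohort[bcc_columns(cfg.n_bcc)],
            cohort["recanalization"].to_numpy(),
            cohort["sex"].to_numpy(),
            partition=part,
            K=K,
            R=R,
            seed=s,
        )
        t, _, p = comp.welch["F_vs_pooled"]
        f_err = comp.results["F"].mean_error
        p_err = comp.results["pooled"].mean_error
        f_errors.append(f_err)
        p_errors.append(p_err)
        hits += int(f_err < p_err and p < 0.05)
    return {
        "female_better_fraction": hits / n_seeds,
        "mean_female_error": float(np.mean(f_errors)),
        "mean_pooled_error": float(np.mean(p_errors)),
        "n_seeds": n_seeds,
    }


def tici_extraction_check(seed: int = 0, n: int = 500) -> dict[str, float]:
    """Extraction accuracy on synthetic reports with planted labels.

    Clean reports must agree with the planted recanalization label exactly;
    reports with zero or conflicting mentions must be routed to manual
    labeling.
    """
    cfg = GeneratorConfig(seed=seed, n_female=n // 2, n_male=n - n // 2,
                          none_rate=0.1, conflict_rate=0.1)
    cohort, _ = generate_cohort(cfg)
    reports, statuses = generate_reports(cohort, cfg)
    table = extract_corpus(reports)
    merged = table.merge(
        cohort[["patient_id", "recanalization"]], on="patient_id", validate="1:1"
    )
    merged["planted_status"] = [statuses[p] for p in merged["patient_id"]]
    clean = merged[merged["planted_status"] == "clean"]
    agree = float((clean["outcome"] == clean["recanalization"]).mean()) * 100.0
    triage = merged[merged["planted_status"].isin(["none", "conflict"])]
    routed = float((triage["outcome"] == "needs_manual").mean()) * 100.0
    return {
        "clean_agreement_pct": agree,
        "triage_routed_pct": routed,
        "n_clean": int(len(clean)),
        "n_triage": int(len(triage)),
    }


def unit_identities() -> dict[str, float]:
    """Small closed-form identities for BH, the Rand index and Welch's t."""
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    p1 = [1, 1, 2, 2]  # {ab|cd}
    p2 = [1, 2, 1, 2]  # {ac|bd}
    rand, _ = rand_index(p1, p2)
    e = np.array([0.41, 0.43, 0.45, 0.40, 0.42])
    t, _, p = welch_t(e, e)
    return {
        "bh_worked_example_q": float(q.max()),
        "bh_worked_example_q_min": float(q.min()),
        "rand_two_partitions": rand,
        "welch_t_identical": t,
        "welch_p_identical": p,
    }
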