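"""Covariate-adjusted logistic models of recanalization success.

Each stable cluster representative is entered (standardized, so the
coefficient is per SD) into a logistic regression of recanalization success
together with the cardiovascular risk factors, antithrombotic medication and
prior intravenous thrombolysis.  Fitting is an in-house iteratively
reweighted least squares (IRLS / Newton-Raphson) routine; the covariance is
the inverse observed information, giving Wald confidence intervals and
p-values.  Analysis is complete-case.  Because a log-odds beta and an odds
ratio are easy to confuse in reports, both scales are emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "hypertension",
    "hyperlipidemia",
    "atrial_fibrillation",
    "diabetes_mellitus",
    "current_smoker",
    "prior_stroke_tia",
    "prior_mi",
    "antiplatelet",
    "doac",
    "ivt",
]


class SeparationError(RuntimeError):
    """Quasi-complete separation: coefficients diverging; consider a penalized fit."""


class RankError(ValueError):
    """Design matrix is rank-deficient."""


@dataclass
class AdjustedEffect:
    cluster: str
    beta: float  # log-odds per SD of the cluster representative
    ci_low: float
    ci_high: float
    p: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    covariates_included: list[str]
    n_used: int


def logistic_irls(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a logistic regression by Newton-Raphson / IRLS.

    Returns (coefficients, covariance) where covariance is the inverse of the
    observed information at the optimum.  Convergence is on the deviance
    change.  Diverging coefficients (|beta| > 15) raise SeparationError.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if np.linalg.matrix_rank(X) < p:
        raise RankError("design matrix is rank-deficient")

    beta = np.zeros(p)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        W = mu * (1.0 - mu)
        info = X.T @ (W[:, None] * X)
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular during IRLS; data may be separated "
                "— consider a penalized (e.g. Firth) fit"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 15:
            raise SeparationError(
                "coefficients diverging (|beta| > 15): quasi-complete separation "
                "— consider a penalized (e.g. Firth) fit"
            )
        dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if abs(dev_old - dev) < tol:
            break
        dev_old = dev
    else:
        warnings.warn("IRLS did not converge; returning last iterate", stacklevel=2)
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    W = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    return beta, cov


def adjusted_cluster_effect(
    cohort: pd.DataFrame,
    representative,
    covariates: list[str] | None = None,
    outcome: str = "recanalization",
    cluster_name: str = "cluster",
    alpha: float = 0.05,
) -> AdjustedEffect:
    """Adjusted per-SD effect of one cluster representative on success.

    Fits success ~ cluster + covariates on complete-case rows.  A negative
    beta means higher representative values associate with unsuccessful
    recanalization.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else list(covariates)
    missing_cols = [c for c in covariates + [outcome] if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks columns {missing_cols}")

    rep = np.asarray(representative, dtype=float)
    df = cohort[[outcome] + covariates].copy()
    df["_rep"] = rep
    n_before = len(df)
    miss_counts = df.isna().sum()
    df = df.dropna()
    n_used = len(df)
    if n_used < n_before:
        logger.info(
            "complete-case filtering dropped %d rows; per-column missing: %s",
            n_before - n_used,
            {c: int(v) for c, v in miss_counts.items() if v > 0},
        )
    n_params = len(covariates) + 2
    if n_used < 10 * n_params:
        warnings.warn(
            f"only {n_used} complete cases for {n_params} parameters "
            "(< 10 per parameter)",
            stacklevel=2,
        )

    y = (df[outcome].astype(str) == "success").to_numpy(float)
    if df[outcome].dtype != object and set(df[outcome].unique()) <= {0, 1}:
        y = df[outcome].to_numpy(float)
    rep_z = (df["_rep"] - df["_rep"].mean()) / df["_rep"].std(ddof=1)
    X = np.column_stack(
        [np.ones(n_used), rep_z.to_numpy(float), df[covariates].to_numpy(float)]
    )
    beta, cov = logistic_irls(X, y)
    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2.0 * float(stats.norm.sf(abs(b / se)))
    return AdjustedEffect(
        cluster=cluster_name,
        beta=b,
        ci_low=b - z * se,
        ci_high=b + z * se,
        p=p,
        odds_ratio=float(np.exp(b)),
        or_ci_low=float(np.exp(b - z * se)),
        or_ci_high=float(np.exp(b + z * se)),
        covariates_included=covariates,
        n_used=n_used,
    )


def adjusted_effects_table(
    cohort: pd.DataFrame,
    representatives: pd.DataFrame,
    clusters: set[str] | list[str],
    covariates: list[str] | None = None,
    outcome: str = "recanalization",
) -> pd.DataFrame:
    """Adjusted effects for a set of stable clusters, as a tidy table."""
    rows = []
    for c in sorted(clusters):
        eff = adjusted_cluster_effect(
            cohort, representatives[c], covariates, outcome=outcome, cluster_name=c
        )
        rows.append(
            {
                "cluster": eff.cluster,
                "beta": eff.beta,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "p": eff.p,
                "odds_ratio": eff.odds_ratio,
                "or_ci_low": eff.or_ci_low,
                "or_ci_high": eff.or_ci_high,
                "n_used": eff.n_used,
            }
        )
    return pd.DataFrame(rows)
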