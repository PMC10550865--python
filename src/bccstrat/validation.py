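"""Repeated stratified cross-validation with stability selection.

The sPLS-DA model is evaluated by K-fold cross-validation repeated R times
(defaults: 5 folds, 100 repeats).  Within every training fold the per-
component sparsity level keepX is tuned by an inner cross-validation, the
model is refitted, the held-out fold is predicted, and the clusters carrying
nonzero component-1 weight are recorded.  A cluster's selection frequency is
the number of fold-fits selecting it divided by K*R, and the stable set
contains clusters whose frequency strictly exceeds the threshold (default
0.9).  Error-rate distributions of pooled versus sex-stratified models are
compared with Welch two-sample t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .clustering import make_representatives
from .splsda import error_rate, fit_splsda, predict

logger = logging.getLogger(__name__)

DEFAULT_KEEPX_GRID = (5, 10, 15, 20, 25, 30)


class ValidationError(ValueError):
    pass


@dataclass
class StabilityResult:
    """Error-rate distribution and per-cluster selection frequencies."""

    error_rates: np.ndarray  # length R, per-repeat mean CV error
    mean_error: float
    sd_error: float
    selection_frequency: dict[str, float]  # component 1, thresholded
    selection_frequency_comp2: dict[str, float]  # reported, not thresholded
    stable_set: set[str]
    threshold: float = 0.9
    K: int = 5
    R: int = 100
    seed: int = 0
    keepX_chosen: list[tuple[int, ...]] = field(default_factory=list, repr=False)


def _inner_error(Xtr, ytr, keepX, ncomp, folds, distance_rule):
    wrong = 0
    for tr, te in folds:
        model = fit_splsda(Xtr[tr], ytr[tr], ncomp=ncomp, keepX=keepX,
                           distance_rule=distance_rule)
        wrong += int(np.sum(predict(model, Xtr[te]) != ytr[te]))
    return wrong / len(ytr)


def _tune_keepX(Xtr, ytr, grid, ncomp, inner_folds, seed, distance_rule):
    """Sequential per-component keepX tuning by inner CV (ties -> sparsest)."""
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(ytr)), ytr))
    chosen: list[int] = []
    for h in range(ncomp):
        best_g, best_err = None, np.inf
        for g in grid:
            err = _inner_error(Xtr, ytr, chosen + [g], h + 1, folds, distance_rule)
            if err < best_err - 1e-12:
                best_g, best_err = g, err
        chosen.append(best_g)
    return chosen


def repeated_cv(
    X,
    y,
    partition: dict[str, int] | None = None,
    K: int = 5,
    R: int = 100,
    seed: int = 0,
    keepX_grid=DEFAULT_KEEPX_GRID,
    ncomp: int = 2,
    threshold: float = 0.9,
    inner_folds: int = 3,
    distance_rule: str = "max_dist",
) -> StabilityResult:
    """Repeated stratified K-fold CV with per-fold keepX tuning.

    ``X`` is either a cluster-representative matrix (``partition=None``) or a
    raw BCC DataFrame together with a variable->cluster ``partition``; in the
    latter case representatives are rebuilt inside every training fold with
    training-fold z-scoring constants, so no test information leaks into the
    standardization.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValidationError(
            f"every class needs >= K={K} members (got {dict(zip(classes, counts))})"
        )
    if partition is not None:
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("partition-based CV needs a DataFrame of raw variables")
        Xdf = X
        feat_names = None  # resolved per fold from the partition
    else:
        if isinstance(X, pd.DataFrame):
            feat_names = list(X.columns)
            Xmat = X.to_numpy(float)
        else:
            Xmat = np.asarray(X, dtype=float)
            feat_names = [f"cluster_{j + 1:02d}" for j in range(Xmat.shape[1])]

    n = len(y)
    sel1: dict[str, int] = {}
    sel2: dict[str, int] = {}
    errors = np.empty(R)
    chosen_log: list[tuple[int, ...]] = []

    for r in range(R):
        fold_seed = (seed * 1009 + r) % (2**31 - 1)
        wrong = 0
        for attempt in range(5):
            skf = StratifiedKFold(n_splits=K, shuffle=True,
                                  random_state=(fold_seed + 1000 * attempt) % (2**31 - 1))
            folds = list(skf.split(np.zeros(n), y))
            if all(np.unique(y[tr]).size == classes.size for tr, _ in folds):
                break
            logger.warning("repeat %d: class missing from a training fold; refolding", r)
        for f, (tr, te) in enumerate(folds):
            if partition is not None:
                reps_tr, means, sds = make_representatives(Xdf.iloc[tr], partition)
                reps_te, _, _ = make_representatives(Xdf.iloc[te], partition, means, sds)
                names = list(reps_tr.columns)
                Xtr = reps_tr.to_numpy(float)
                Xte = reps_te.to_numpy(float)
            else:
                names = feat_names
                Xtr, Xte = Xmat[tr], Xmat[te]
            p = Xtr.shape[1]
            grid = sorted({min(g, p) for g in keepX_grid})
            ncomp_eff = min(ncomp, p)
            keepX = _tune_keepX(Xtr, y[tr], grid, ncomp_eff, inner_folds,
                                (fold_seed + f) % (2**31 - 1), distance_rule)
            model = fit_splsda(Xtr, y[tr], ncomp=ncomp_eff, keepX=keepX,
                               distance_rule=distance_rule)
            wrong += int(np.sum(predict(model, Xte) != y[te]))
            chosen_log.append(tuple(keepX))
            for j in np.flatnonzero(model.weights[:, 0]):
                sel1[names[j]] = sel1.get(names[j], 0) + 1
            if ncomp_eff > 1:
                for j in np.flatnonzero(model.weights[:, 1]):
                    sel2[names[j]] = sel2.get(names[j], 0) + 1
        errors[r] = wrong / n

    denom = K * R
    freq1 = {c: cnt / denom for c, cnt in sorted(sel1.items())}
    freq2 = {c: cnt / denom for c, cnt in sorted(sel2.items())}
    stable = {c for c, fq in freq1.items() if fq > threshold}
    return StabilityResult(
        error_rates=errors,
        mean_error=float(errors.mean()),
        sd_error=float(errors.std(ddof=1)) if R > 1 else 0.0,
        selection_frequency=freq1,
        selection_frequency_comp2=freq2,
        stable_set=stable,
        threshold=threshold,
        K=K,
        R=R,
        seed=seed,
        keepX_chosen=chosen_log,
    )


def welch_t(e1, e2) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(e1, dtype=float)
    b = np.asarray(e2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 values")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValidationError("both samples have zero variance")
    n1, n2 = a.size, b.size
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


@dataclass
class StratifiedComparison:
    """Pooled vs female-only vs male-only CV results with Welch contrasts."""

    results: dict[str, StabilityResult]  # keys: pooled, F, M
    welch: dict[str, tuple[float, float, float]]  # e.g. "F_vs_pooled" -> (t, df, p)


def stratified_comparison(
    X,
    y,
    sex,
    partition: dict[str, int] | None = None,
    **cv_kwargs,
) -> StratifiedComparison:
    """Run repeated CV on pooled, female-only and male-only data.

    All three models share the same settings; error distributions are
    compared pairwise with Welch t-tests.
    """
    sex = np.asarray(sex)
    y = np.asarray(y)
    if set(np.unique(sex)) - {"F", "M"}:
        raise ValidationError("sex labels must be 'F'/'M'")
    if "F" not in sex or "M" not in sex:
        raise ValidationError("both sexes must be present")

    def subset(mask):
        Xs = X.loc[mask].reset_index(drop=True) if isinstance(X, pd.DataFrame) else X[mask]
        return Xs, y[np.asarray(mask)]

    results = {}
    results["pooled"] = repeated_cv(X, y, partition=partition, **cv_kwargs)
    for label, m in (("F", sex == "F"), ("M", sex == "M")):
        Xs, ys = subset(m)
        results[label] = repeated_cv(Xs, ys, partition=partition, **cv_kwargs)
    welch = {
        "F_vs_pooled": welch_t(results["F"].error_rates, results["pooled"].error_rates),
        "M_vs_pooled": welch_t(results["M"].error_rates, results["pooled"].error_rates),
        "F_vs_M": welch_t(results["F"].error_rates, results["M"].error_rates),
    }
    return StratifiedComparison(results=results, welch=welch)
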