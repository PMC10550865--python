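"""Sparse partial least squares discriminant analysis (sPLS-DA), from scratch.

PLS-DA regresses a dummy-coded class matrix Y on predictors X by NIPALS,
extracting successive latent components t_h = X w_h that maximize covariance
with Y.  The sparse variant soft-thresholds each weight vector so that only
``keepX[h]`` predictors carry nonzero weight on component h, which is the
variable-selection mechanism the stability analysis downstream counts.

The implementation follows the soft-thresholded NIPALS formulation: per
component, iterate

    w <- X' u / ||X' u||,  w <- soft_threshold(w, keepX),  t <- X w,
    q <- Y' t / ||Y' t||,  u <- Y q

to convergence, then deflate X (and Y) by regression on t.  The sign of each
weight vector is fixed so its largest-magnitude entry is positive, making
fits reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class SplsdaError(ValueError):
    pass


def dummy_code(y) -> tuple[np.ndarray, np.ndarray]:
    """Dummy-code class labels into an n x C indicator matrix.

    Classes are ordered by first appearance, so "first class" tie-breaks are
    deterministic and follow the input.
    """
    y = np.asarray(y)
    classes = np.array(list(dict.fromkeys(y.tolist())))
    if classes.size < 2:
        raise SplsdaError("need at least two classes")
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def soft_threshold(v, keep: int) -> np.ndarray:
    """Soft-threshold a vector to exactly ``keep`` nonzeros, then renormalize.

    The threshold is the (keep+1)-th largest magnitude; surviving entries are
    shrunk toward zero by it.  Exact magnitude ties at the boundary are broken
    by first index (the retained set keeps its original values in that case,
    so the count stays exact).
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if not (1 <= keep <= n):
        raise SplsdaError(f"keep={keep} out of range 1..{n}")
    order = np.argsort(-np.abs(v), kind="stable")
    lam = 0.0 if keep == n else abs(v[order[keep]])
    out = np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)
    if np.count_nonzero(out) < keep and np.count_nonzero(v) >= keep:
        # boundary tie: fall back to hard thresholding of the stable top-keep
        out = np.zeros_like(v)
        sel = order[:keep]
        out[sel] = v[sel]
    nrm = np.linalg.norm(out)
    if nrm == 0:
        raise SplsdaError("soft thresholding annihilated the weight vector")
    return out / nrm


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model."""

    ncomp: int
    keepX: list[int]
    classes: np.ndarray
    weights: np.ndarray  # p x ncomp, per-component sparse weight vectors
    x_loadings: np.ndarray  # p x ncomp
    y_loadings: np.ndarray  # C x ncomp
    x_scores: np.ndarray  # n x ncomp
    class_centroids: np.ndarray  # C x ncomp mean score vectors
    train_means: np.ndarray
    train_sds: np.ndarray
    y_means: np.ndarray  # column means of the dummy matrix
    distance_rule: str = "max_dist"
    feature_names: list[str] | None = None
    within_cov: np.ndarray | None = field(default=None, repr=False)  # for mahalanobis


def _standardize(X: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (X - means) / sds


def fit_splsda(
    X,
    y,
    ncomp: int = 2,
    keepX=None,
    distance_rule: str = "max_dist",
    standardize: bool = True,
    tol: float = 1e-9,
    max_iter: int = 500,
    feature_names: list[str] | None = None,
) -> SplsdaModel:
    """Fit sparse PLS-DA.  X must be complete (impute/complete-case upstream)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.isnan(X).any():
        raise SplsdaError("X contains missing values; handle them upstream")
    if n <= ncomp:
        raise SplsdaError("need n > ncomp samples")
    if keepX is None:
        keepX = [p] * ncomp
    elif np.isscalar(keepX):
        keepX = [int(keepX)] * ncomp
    else:
        keepX = [int(k) for k in keepX]
    if len(keepX) != ncomp:
        raise SplsdaError("keepX must have one entry per component")
    if any(k < 1 or k > p for k in keepX):
        raise SplsdaError(f"keepX entries must lie in 1..{p}")
    if distance_rule not in ("max_dist", "centroid", "mahalanobis"):
        raise SplsdaError(f"unknown distance rule {distance_rule!r}")

    Y, classes = dummy_code(y)
    if standardize:
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        sds = np.where(sds == 0, 1.0, sds)
    else:
        means = np.zeros(p)
        sds = np.ones(p)
    Xd = _standardize(X, means, sds)
    y_means = Y.mean(axis=0)
    Yd = Y - y_means

    C = classes.size
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros((C, ncomp))
    T = np.zeros((n, ncomp))

    for h in range(ncomp):
        u = Yd[:, 0].copy()
        if not u.any():
            u = Yd[:, np.argmax(np.var(Yd, axis=0))].copy()
        w_old = np.zeros(p)
        converged = False
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise SplsdaError("degenerate component: X'u vanished")
            w /= nw
            w = soft_threshold(w, keepX[h])
            t = Xd @ w
            q = Yd.T @ t
            nq = np.linalg.norm(q)
            if nq == 0:
                raise SplsdaError("degenerate component: Y't vanished")
            q /= nq
            u = Yd @ q
            if np.linalg.norm(w - w_old) < tol:
                converged = True
                break
            w_old = w
        if not converged:
            warnings.warn(
                f"component {h + 1} did not converge in {max_iter} iterations; "
                "using best iterate",
                stacklevel=2,
            )
        # sign convention: largest-magnitude weight entry positive
        top = np.argmax(np.abs(w))
        if w[top] < 0:
            w, t = -w, -t
        tt = t @ t
        p_load = Xd.T @ t / tt
        q_load = Yd.T @ t / tt
        W[:, h] = w
        P[:, h] = p_load
        Q[:, h] = q_load
        T[:, h] = t
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, q_load)

    idx = Y.argmax(axis=1)  # class index per sample
    counts = Y.sum(axis=0)
    centroids = (Y.T @ T) / counts[:, None]
    # pooled within-class covariance of scores (for the mahalanobis rule)
    resid = T - centroids[idx]
    dof = max(n - C, 1)
    within = resid.T @ resid / dof

    return SplsdaModel(
        ncomp=ncomp,
        keepX=keepX,
        classes=classes,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        class_centroids=centroids,
        train_means=means,
        train_sds=sds,
        y_means=y_means,
        distance_rule=distance_rule,
        feature_names=list(feature_names) if feature_names is not None else None,
        within_cov=within,
    )


def transform(model: SplsdaModel, Xnew) -> np.ndarray:
    """Project new samples into the model's score space (with deflation)."""
    Xn = np.asarray(Xnew, dtype=float)
    if Xn.ndim == 1:
        Xn = Xn[None, :]
    if Xn.shape[1] != model.weights.shape[0]:
        raise SplsdaError(
            f"expected {model.weights.shape[0]} features, got {Xn.shape[1]}"
        )
    Xd = _standardize(Xn, model.train_means, model.train_sds)
    T = np.zeros((Xd.shape[0], model.ncomp))
    for h in range(model.ncomp):
        t = Xd @ model.weights[:, h]
        T[:, h] = t
        Xd = Xd - np.outer(t, model.x_loadings[:, h])
    return T


def predict(model: SplsdaModel, Xnew, distance_rule: str | None = None) -> np.ndarray:
    """Assign class labels to new samples.

    ``max_dist`` (default) assigns the class whose predicted dummy value is
    largest; ``centroid`` the nearest class centroid in score space;
    ``mahalanobis`` the nearest centroid under the pooled within-class score
    covariance.  Ties break deterministically to the first class label.
    """
    rule = distance_rule or model.distance_rule
    T = transform(model, Xnew)
    if rule == "max_dist":
        Yhat = model.y_means + T @ model.y_loadings.T
        idx = np.argmax(Yhat, axis=1)
    elif rule == "centroid":
        d = ((T[:, None, :] - model.class_centroids[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d, axis=1)
    elif rule == "mahalanobis":
        cov = model.within_cov
        cov = cov + 1e-12 * np.eye(cov.shape[0])
        ci = np.linalg.inv(cov)
        diff = T[:, None, :] - model.class_centroids[None, :, :]
        d = np.einsum("nci,ij,ncj->nc", diff, ci, diff)
        idx = np.argmin(d, axis=1)
    else:
        raise SplsdaError(f"unknown distance rule {rule!r}")
    return model.classes[idx]


def error_rate(pred, truth) -> float:
    """Misclassification fraction: mismatches divided by total samples."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0:
        raise SplsdaError("empty prediction vector")
    if pred.shape != truth.shape:
        raise SplsdaError("prediction and truth lengths differ")
    return float(np.mean(pred != truth))
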