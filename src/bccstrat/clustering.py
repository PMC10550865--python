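"""Clustering of collinear blood cell characteristics.

Highly collinear BCCs are grouped by average-linkage hierarchical clustering
on the distance 1 - |Spearman correlation|.  The number of clusters k is
chosen by sex concordance: for each candidate k the women-only and men-only
correlation matrices are clustered separately, and the k maximizing the
adjusted Rand index between the two partitions wins (ties break to the
smallest k).  Each cluster is then summarized by a synthetic representative
variable, the mean of its z-scored members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform


class ClusterError(ValueError):
    pass


@dataclass
class ClusterModel:
    """A variable partition with its sex-concordance score and representatives."""

    partition: dict[str, int]  # variable name -> cluster id (1..k)
    k: int
    concordance: float  # Rand index between female- and male-derived partitions
    concordance_adjusted: float
    representatives: pd.DataFrame  # patients x k
    rep_means: dict[str, np.ndarray]  # per-variable z-scoring constants
    rep_sds: dict[str, np.ndarray]


def correlation_distance(X: pd.DataFrame) -> np.ndarray:
    """Distance matrix d(i,j) = 1 - |rho_Spearman(i,j)| (pairwise-complete).

    A constant column has undefined correlation; it is placed at distance 1
    from every other variable, with a warning.
    """
    corr = X.corr(method="spearman").to_numpy()
    if np.isnan(corr).any():
        const = [c for c in X.columns if X[c].dropna().nunique() <= 1]
        if const:
            warnings.warn(
                f"constant column(s) {const}: distance set to 1 against all others",
                stacklevel=2,
            )
        corr = np.nan_to_num(corr, nan=0.0)
    D = 1.0 - np.abs(corr)
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, None)


def _linkage_from_distance(D: np.ndarray) -> np.ndarray:
    return linkage(squareform(D, checks=False), method="average")


def cluster_variables(D: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage tree over D into exactly k clusters (labels 1..k)."""
    p = D.shape[0]
    if not (1 <= k <= p):
        raise ClusterError(f"k={k} out of range 1..{p}")
    Z = _linkage_from_distance(D)
    labels = cut_tree(Z, n_clusters=k).ravel()
    return labels + 1


def rand_index(p1, p2) -> tuple[float, float]:
    """Pair-counting Rand index and adjusted Rand index of two partitions."""
    a = np.asarray(p1)
    b = np.asarray(p2)
    if a.shape != b.shape or a.ndim != 1:
        raise ClusterError("partitions must be equal-length label vectors")
    n = a.size
    if n < 2:
        raise ClusterError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    # agreements = pairs together in both + pairs apart in both
    rand = (total + 2 * sum_ij - sum_a - sum_b) / total
    expected = sum_a * sum_b / total
    max_idx = 0.5 * (sum_a + sum_b)
    denom = max_idx - expected
    ari = 1.0 if denom == 0 else (sum_ij - expected) / denom
    return float(rand), float(ari)


def select_k(
    X: pd.DataFrame,
    sex_labels,
    k_grid,
    criterion: str = "sex_concordance",
    n_boot: int = 20,
    seed: int = 0,
) -> ClusterModel:
    """Choose the number of clusters and fit the final pooled partition.

    Default criterion clusters the women-only and men-only data separately
    at each k and picks the k maximizing the adjusted Rand index between the
    two partitions.  A bootstrap-stability criterion (average ARI between
    partitions of resampled patient sets) is available as an alternative.
    """
    sex = np.asarray(sex_labels)
    k_grid = sorted(set(int(k) for k in k_grid))
    p = X.shape[1]
    if any(k < 1 or k > p for k in k_grid):
        raise ClusterError("k_grid outside 1..n_variables")

    if criterion == "sex_concordance":
        masks = [sex == "F", sex == "M"]
        if any(m.sum() < 3 for m in masks):
            raise ClusterError("both sexes must have at least 3 patients")
        trees = [_linkage_from_distance(correlation_distance(X.loc[m])) for m in masks]
        cuts = [cut_tree(Z, n_clusters=k_grid) for Z in trees]
        scores = []
        for j, k in enumerate(k_grid):
            _, ari = rand_index(cuts[0][:, j], cuts[1][:, j])
            scores.append(ari)
    elif criterion == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = [rng.integers(0, len(X), len(X)) for _ in range(n_boot)]
        trees = [_linkage_from_distance(correlation_distance(X.iloc[i])) for i in idx]
        cuts = [cut_tree(Z, n_clusters=k_grid) for Z in trees]
        scores = []
        for j, k in enumerate(k_grid):
            aris = [
                rand_index(cuts[a][:, j], cuts[b][:, j])[1]
                for a in range(n_boot)
                for b in range(a + 1, n_boot)
            ]
            scores.append(float(np.mean(aris)))
    else:
        raise ClusterError(f"unknown criterion {criterion!r}")

    best = int(np.argmax(scores))  # argmax returns the first (smallest k) on ties
    k_star = k_grid[best]

    # concordance (plain Rand + ARI) at the chosen k, female vs male
    fm_masks = [sex == "F", sex == "M"]
    fm_parts = [
        cluster_variables(correlation_distance(X.loc[m]), k_star) for m in fm_masks
    ]
    rand, ari = rand_index(fm_parts[0], fm_parts[1])

    pooled_labels = cluster_variables(correlation_distance(X), k_star)
    partition = {v: int(c) for v, c in zip(X.columns, pooled_labels)}
    reps, means, sds = make_representatives(X, partition)
    return ClusterModel(
        partition=partition,
        k=k_star,
        concordance=rand,
        concordance_adjusted=ari,
        representatives=reps,
        rep_means=means,
        rep_sds=sds,
    )


def make_representatives(
    X: pd.DataFrame,
    partition: dict[str, int],
    means: dict | None = None,
    sds: dict | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Build cluster representative variables: mean of z-scored members.

    Singleton clusters pass through z-scored.  When ``means``/``sds`` are
    given (training-set constants, e.g. inside cross-validation) they are
    applied instead of being recomputed, so no test-fold information leaks
    into the standardization.  Zero-SD members are excluded with a warning.
    """
    missing = [v for v in X.columns if v not in partition]
    if missing:
        raise ClusterError(f"partition does not cover variables {missing[:5]}")
    if means is None:
        Xall = X.to_numpy(float)
        mu_vec = np.nanmean(Xall, axis=0)
        sd_vec = np.nanstd(Xall, axis=0, ddof=1)
        means = dict(zip(X.columns, mu_vec))
        sds = dict(zip(X.columns, sd_vec))
    cols = list(X.columns)
    mu = np.array([means[v] for v in cols])
    sd = np.array([sds[v] for v in cols])
    usable = (sd != 0) & np.isfinite(sd)
    clusters = sorted(set(partition[v] for v in cols))
    if not usable.all():
        bad = [v for v, u in zip(cols, usable) if not u]
        warnings.warn(f"zero-SD member(s) {bad} excluded from representatives", stacklevel=2)
    Xm = X.to_numpy(float)
    Z = (Xm - mu) / np.where(usable, sd, 1.0)
    labels = np.array([partition[v] for v in cols])
    names = [f"cluster_{c:02d}" for c in clusters]
    if np.isnan(Xm).any():
        rep_mat = np.empty((len(X), len(clusters)))
        for j, c in enumerate(clusters):
            m = (labels == c) & usable
            rep_mat[:, j] = np.nanmean(Z[:, m], axis=1) if m.any() else 0.0
    else:
        # membership matrix, columns normalized by member count
        M = np.zeros((len(cols), len(clusters)))
        for j, c in enumerate(clusters):
            m = (labels == c) & usable
            if m.any():
                M[m, j] = 1.0 / m.sum()
        rep_mat = Z @ M
    out = pd.DataFrame(rep_mat, columns=names, index=X.index)
    return out, means, sds


def partition_to_frame(partition: dict[str, int]) -> pd.DataFrame:
    """Two-column (variable, cluster) table, plus usable as the S1-style map."""
    return pd.DataFrame(
        {"variable": list(partition), "cluster": [partition[v] for v in partition]}
    ).sort_values(["cluster", "variable"], ignore_index=True)
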