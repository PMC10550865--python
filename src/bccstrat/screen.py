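"""Univariate sex comparisons of blood cell characteristics with FDR control.

Each BCC is compared between women and men with a two-sided Mann-Whitney U
test (lab values are typically skewed, and the field reports medians/IQRs);
a Welch t-test is available behind a switch.  P-values across variables are
adjusted with the Benjamini-Hochberg step-up procedure, and a variable is
declared sex-different at q < 0.05.  A Pearson chi-square on 2x2 tables
covers the baseline contingency comparisons (e.g. recanalization success by
sex).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ScreenError(ValueError):
    pass


@dataclass
class ScreenResult:
    variable: str
    stat: float
    p: float
    median_F: float
    median_M: float
    iqr_F: tuple[float, float]
    iqr_M: tuple[float, float]
    q: float = float("nan")
    significant: bool = False


def compare_by_sex(cohort: pd.DataFrame, variable: str, test: str = "mannwhitney") -> ScreenResult:
    """Compare one variable between sexes (pre-adjustment).

    Returns the test statistic, two-sided p-value, and per-sex medians and
    IQRs.  A column constant across all patients yields p = 1 by convention.
    """
    x = cohort.loc[cohort["sex"] == "F", variable].dropna().to_numpy(float)
    y = cohort.loc[cohort["sex"] == "M", variable].dropna().to_numpy(float)
    if x.size == 0 and y.size == 0:
        raise ScreenError(f"variable {variable!r} is entirely missing")
    if x.size < 2 or y.size < 2:
        raise ScreenError(f"variable {variable!r} needs >= 2 non-missing values per sex")

    def iqr(a: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(a, 25)), float(np.percentile(a, 75)))

    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        stat_val, p = float("nan"), 1.0
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat_val, p = float(res.statistic), float(res.pvalue)
    elif test == "ttest":
        res = stats.ttest_ind(x, y, equal_var=False)
        stat_val, p = float(res.statistic), float(res.pvalue)
    else:
        raise ScreenError(f"unknown test {test!r}")
    return ScreenResult(
        variable=variable,
        stat=stat_val,
        p=min(p, 1.0),
        median_F=float(np.median(x)),
        median_M=float(np.median(y)),
        iqr_F=iqr(x),
        iqr_M=iqr(y),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1;
    invariant to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ScreenError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ScreenError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, int]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Closed form N(ad - bc)^2 / (r1 r2 c1 c2); p from the chi-square
    distribution with 1 df.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ScreenError("counts must be nonnegative")
    n = counts.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ScreenError("all margins of the 2x2 table must be positive")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p, 1


def screen_cohort(
    cohort: pd.DataFrame, variables: list[str], alpha: float = 0.05, test: str = "mannwhitney"
) -> pd.DataFrame:
    """Run the sex screen over all variables and BH-adjust across them."""
    results = [compare_by_sex(cohort, v, test=test) for v in variables]
    q = bh_adjust([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
        r.significant = bool(qv < alpha)
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "stat": [r.stat for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
            "median_F": [r.median_F for r in results],
            "median_M": [r.median_M for r in results],
            "iqr_F_low": [r.iqr_F[0] for r in results],
            "iqr_F_high": [r.iqr_F[1] for r in results],
            "iqr_M_low": [r.iqr_M[0] for r in results],
            "iqr_M_high": [r.iqr_M[1] for r in results],
        }
    )
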