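"""Validation statistics: Spearman, ICC(3,1), Friedman, Wilcoxon signed-rank,
and the most-avid-lesion selection rule.

Each test is implemented from its rank/ANOVA definition, with exact
(enumeration) p-values at small n and the usual asymptotic approximations
otherwise. The exact variants double as oracles for the asymptotic ones.
All p-values are two-sided unless an ``alternative`` is passed.
"""

from __future__ import annotations

import itertools
import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

Alternative = Literal["two-sided", "greater", "less"]


def most_avid_per_subject(
    table: pd.DataFrame,
    subject_col: str = "subject",
    suv_col: str = "suv_45_60",
    region_col: str = "region",
) -> pd.DataFrame:
    """Keep one lesion per subject: the highest late-window SUV.

    Avoids treating multiple lesions from one subject as independent in
    the correlation analyses. Ties break deterministically by region label.
    """
    if table[suv_col].isna().any():
        raise ValueError(f"missing values in {suv_col}")
    ordered = table.sort_values(
        [subject_col, suv_col, region_col], ascending=[True, False, True],
        kind="mergesort",
    )
    return ordered.groupby(subject_col, sort=True).head(1).reset_index(drop=True)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    method: Literal["auto", "exact", "asymptotic"] = "auto",
    exact_max_n: int = 9,
) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    p-value: exact permutation (all n! orderings of y) for n <= 9 under
    ``auto``, else the t-approximation
    t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df. Two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = _rank_corr(rx, ry)

    if method == "exact" or (method == "auto" and n <= exact_max_n):
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = np.sqrt((pc * pc).sum(axis=1) * float(rxc @ rxc))
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return rho, p


def icc3(ratings: np.ndarray) -> tuple[float, float]:
    """ICC(3,1): two-way mixed-effects, single-measure, consistency.

    ``ratings`` is an n_targets x k_raters matrix with no missing cells.
    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E) from the two-way ANOVA
    decomposition; p from F = MS_R/MS_E on (n-1, (n-1)(k-1)) df.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 targets and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not allowed (no imputation)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((m - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_e <= 0:
        return 1.0, 0.0
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    f = ms_r / ms_e
    p = float(f_dist.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a matrix of within-row ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0  # every row fully tied: no information
    return chisq / c


def friedman(
    values: np.ndarray,
    method: Literal["auto", "exact", "asymptotic"] = "auto",
    exact_max_n: int = 5,
) -> tuple[float, float]:
    """Friedman test across k >= 3 repeated conditions, n >= 2 subjects.

    Tie correction by mid-ranks; p from chi-square on k-1 df, or exact
    enumeration over all (k!)^n within-row orderings for n <= 5.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError("values must be a 2-D matrix")
    n, k = m.shape
    if n < 2 or k < 3:
        raise ValueError("need >= 2 subjects and >= 3 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete matrix")
    ranks = np.vstack([rankdata(row) for row in m])
    stat = _friedman_statistic(ranks)
    if stat == 0.0 and np.allclose(ranks, ranks[:, :1]):
        return 0.0, 1.0

    if method == "exact" or (method == "auto" and n <= exact_max_n):
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        for assignment in itertools.product(perms, repeat=n):
            r = np.vstack([ranks[i, list(perm)] for i, perm in enumerate(assignment)])
            if _friedman_statistic(r) >= stat - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(chi2_dist.sf(stat, k - 1))
    return float(stat), p


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    alternative: Alternative = "two-sided",
    method: Literal["auto", "exact", "asymptotic"] = "auto",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties get mid-ranks. The statistic is W+,
    the sum of ranks of positive differences. Exact p enumerates all 2^n
    sign assignments for n <= 12; otherwise a normal approximation with
    continuity correction and tie-adjusted variance is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D arrays")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("need >= 5 nonzero differences")
    r = rankdata(np.abs(d))
    w_plus = float(np.sum(r[d > 0]))
    mean_w = n * (n + 1) / 4.0

    if method == "exact" or (method == "auto" and n <= exact_max_n):
        # distribution of W+ over all sign assignments of the observed ranks
        signs = np.array(list(itertools.product([0.0, 1.0], repeat=n)))
        w_all = signs @ r
        if alternative == "greater":
            p = float(np.mean(w_all >= w_plus - 1e-12))
        elif alternative == "less":
            p = float(np.mean(w_all <= w_plus + 1e-12))
        else:
            dev = abs(w_plus - mean_w)
            p = float(np.mean(np.abs(w_all - mean_w) >= dev - 1e-12))
    else:
        _, counts = np.unique(r, return_counts=True)
        var_w = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(counts**3 - counts)) / 48.0
        sd = math.sqrt(var_w)
        if alternative == "greater":
            z = (w_plus - mean_w - 0.5) / sd
            p = float(norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mean_w + 0.5) / sd
            p = float(norm.cdf(z))
        else:
            z = (abs(w_plus - mean_w) - 0.5) / sd
            p = 2.0 * float(norm.sf(z))
    return w_plus, min(p, 1.0)
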