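"""Nonparametric group comparisons of PC scores across clusters.

Kruskal-Wallis (tie-corrected H, chi-square reference with k-1 df) per
component, with the all-pairs Steel-Dwass post hoc: each pair's tie-corrected
rank statistic is referred to the studentized-range distribution with k groups
and infinite degrees of freedom, which controls the familywise error across
the k(k-1)/2 comparisons.  The effect size reported alongside H is
r = sqrt(H / (N - 1)); the formula is carried in the result so the convention
is unambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupTestResult:
    statistic: float  # tie-corrected Kruskal-Wallis H
    df: int
    p_value: float
    effect_size_r: float
    effect_size_formula: str
    n: int
    degenerate: bool = False  # all values tied: H undefined, p reported as 1


def chi_square_tail(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-square reference distribution, the
    form in which Kruskal-Wallis results are reported."""
    return float(sps.chi2.sf(statistic, df))


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis test of k independent groups."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    n = len(values)
    df = len(labels) - 1
    if np.all(values == values[0]):
        return GroupTestResult(np.nan, df, 1.0, np.nan,
                               "r = sqrt(H / (N - 1))", n, degenerate=True)
    h, _ = sps.kruskal(*samples)
    p = chi_square_tail(h, df)
    r = float(np.sqrt(h / (n - 1)))
    return GroupTestResult(float(h), df, p, r, "r = sqrt(H / (N - 1))", n)


def kruskal_wallis_by_pc(scores: pd.DataFrame, assignments: np.ndarray) -> dict[str, GroupTestResult]:
    """One Kruskal-Wallis test per PC column against the cluster labels."""
    return {col: kruskal_wallis(scores[col].to_numpy(float), assignments)
            for col in scores.columns}


def _pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for one pair."""
    ni, nj = len(x), len(y)
    n = ni + nj
    ranks = sps.rankdata(np.concatenate([x, y]))
    ri = ranks[:ni].sum()
    expected = ni * (n + 1) / 2.0
    # tie-corrected variance of the rank sum
    var = ni * nj / (n * (n - 1.0)) * ((ranks ** 2).sum() - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((ri - expected) / np.sqrt(var))


def steel_dwass(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """All-pairs Steel-Dwass comparisons.

    Returns a symmetric k x k matrix of p-values with a unit diagonal;
    p = P(Q_{k,inf} > sqrt(2) |t|) with Q the studentized range.  For k = 2
    this reduces to the two-sided tie-corrected rank-sum test.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    p = np.eye(k)  # diagonal = 1 (a group vs itself)
    p[np.diag_indices(k)] = 1.0
    for (i, gi), (j, gj) in itertools.combinations(enumerate(labels), 2):
        t = _pair_statistic(values[groups == gi], values[groups == gj])
        pij = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf))
        p[i, j] = p[j, i] = min(1.0, pij)
    return pd.DataFrame(p, index=labels, columns=labels)


def steel_dwass_by_pc(scores: pd.DataFrame, assignments: np.ndarray) -> dict[str, pd.DataFrame]:
    return {col: steel_dwass(scores[col].to_numpy(float), assignments)
            for col in scores.columns}


def vsn_prevalence(cluster_sizes, cluster_vsn_pct) -> float:
    """Overall neglect prevalence (%) implied by per-cluster sizes and
    per-cluster %VSN: nearest-integer affected counts summed over clusters,
    divided by the cohort size."""
    sizes = np.asarray(cluster_sizes, float)
    pct = np.asarray(cluster_vsn_pct, float)
    if sizes.shape != pct.shape:
        raise ValueError("sizes and percentages must align")
    affected = np.rint(sizes * pct / 100.0)
    return round(100.0 * affected.sum() / sizes.sum(), 2)
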