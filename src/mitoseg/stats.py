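"""Statistical comparison of morphometry and accuracy tables.

The battery mirrors common practice for non-normal morphology data:
samples are first screened with D'Agostino's K-squared normality test;
two groups are compared with an independent two-sample t-test when both
pass (p > alpha) and with the Mann-Whitney U test otherwise; three or
more groups go through the Kruskal-Wallis H test (tie-corrected) followed,
when significant, by Dunn's pairwise z-tests with Bonferroni adjustment
(Holm or none are available too).  All tests are two-sided; ties receive
average ranks.  Every result records which branch (parametric or
nonparametric) was chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "normality_test", "compare_two", "compare_multi",
           "dunn_posthoc", "correlate"]

MIN_NORMALITY_N = 8  # D'Agostino's K-squared needs a moderate sample


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    chosen_branch: str = "nonparametric"  # or "parametric"
    post_hoc: pd.DataFrame | None = None


def normality_test(sample) -> TestResult:
    """D'Agostino's K-squared test of normality.

    K^2 is the sum of squared z-scores of sample skewness and kurtosis,
    referred to a chi-square distribution with 2 degrees of freedom.
    Requires n >= 8; smaller samples raise so callers fall back to the
    nonparametric branch explicitly.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < MIN_NORMALITY_N:
        raise ValueError(f"normality test needs n >= {MIN_NORMALITY_N}, got {x.size}")
    stat, p = sps.normaltest(x)
    return TestResult("dagostino_k2", float(stat), float(p), (x.size,))


def compare_two(sample_a, sample_b, alpha: float = 0.05) -> TestResult:
    """Two-group comparison with a normality gate.

    Both samples normal at ``alpha`` -> independent two-sample t-test;
    otherwise (including samples too small to screen) -> Mann-Whitney U.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare_two needs n >= 3 per group")
    try:
        normal = (normality_test(a).p_value > alpha
                  and normality_test(b).p_value > alpha)
    except ValueError:
        normal = False
    if normal:
        stat, p = sps.ttest_ind(a, b)
        return TestResult("t_test_ind", float(stat), float(p), (a.size, b.size),
                          chosen_branch="parametric")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      (a.size, b.size), chosen_branch="nonparametric")


def _tie_correction_term(all_values: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups, used by Dunn's variance."""
    _, counts = np.unique(all_values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def dunn_posthoc(samples: list[np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T the tie term; two-sided normal p-values, multiplicity-adjusted
    (``bonferroni``, ``holm`` or ``none``).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + s.size].mean())
        sizes.append(s.size)
        start += s.size
    tie_term = _tie_correction_term(pooled) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": i, "group_b": j, "z": z, "p": min(1.0, p)})
    table = pd.DataFrame(rows)
    m = len(table)
    if adjust == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p"] * m)
    elif adjust == "holm":
        order = np.argsort(table["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adjusted"] = adj
    elif adjust == "none":
        table["p_adjusted"] = table["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def compare_multi(samples, alpha: float = 0.05,
                  adjust: str = "bonferroni") -> TestResult:
    """Kruskal-Wallis H across >= 3 groups, Dunn's post hoc if significant."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 3:
        raise ValueError("compare_multi needs >= 3 groups (use compare_two)")
    if any(s.size < 3 for s in samples):
        raise ValueError("each group needs n >= 3")
    try:
        stat, p = sps.kruskal(*samples)
    except ValueError:
        # scipy rejects all-identical data; H is 0 there by definition
        stat, p = 0.0, 1.0
    post = dunn_posthoc(samples, adjust=adjust) if p < alpha else None
    return TestResult("kruskal_wallis", float(stat), float(p),
                      tuple(s.size for s in samples),
                      chosen_branch="nonparametric", post_hoc=post)


def correlate(table: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise feature correlation matrix (pearson or spearman).

    Uses pairwise-complete observations; constant features yield NaN
    entries rather than a spurious 0 or 1.  The diagonal is 1 for any
    non-constant feature.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[0] < 3:
        raise ValueError("need >= 3 observations")
    if numeric.shape[1] < 2:
        raise ValueError("need >= 2 numeric features")
    return numeric.corr(method=method, min_periods=3)
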