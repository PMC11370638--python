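"""Variance-gated group comparisons with post hoc letter displays.

The comparison scheme used throughout the infection experiments: Levene's
test (mean-centered) decides at alpha = 0.05 between the parametric branch
(pooled two-sample Student t, or one-way ANOVA followed by Tukey's HSD) and
the rank-based branch (Wilcoxon rank-sum, or Kruskal-Wallis followed by
Dunn's test with multiplicity adjustment).  Post hoc tables carry a compact
letter display: groups sharing a letter are not significantly different at
the family-wise error rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "variance_gate",
    "compare_two",
    "compare_two_from_summary",
    "compare_many",
    "gated_compare",
    "dunn_test",
    "compact_letter_display",
]

Branch = Literal["parametric", "rank"]


@dataclass
class ComparisonResult:
    branch: Branch
    test: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    posthoc: pd.DataFrame | None = None
    letters: dict[str, str] | None = None
    gate_p: float | None = None


def variance_gate(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> Branch:
    """Levene's test (mean-centered) for homogeneity of variances.

    Homogeneous variances (p >= alpha) select the parametric branch,
    otherwise the rank-based branch.
    """
    branch, _ = _gate(groups, alpha)
    return branch


def _gate(groups: Sequence[Sequence[float]], alpha: float) -> tuple[Branch, float]:
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    if all(np.ptp(g) == 0 for g in arrs):
        # all groups internally constant: Levene statistic is 0/0; variances
        # are trivially homogeneous
        return "parametric", 1.0
    stat, p = stats.levene(*arrs, center="mean")
    if math.isnan(p):
        return "parametric", 1.0
    return ("parametric" if p >= alpha else "rank"), float(p)


def _pooled_t(m1, s1, n1, m2, s2, n2) -> tuple[float, float, int]:
    """Pooled-variance Student t from summary statistics (closed form)."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if m1 == m2:
            return 0.0, 1.0, df
        return math.copysign(math.inf, m1 - m2), 0.0, df
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p, df


def compare_two_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> ComparisonResult:
    """Pooled two-sample Student t from (mean, sd, n) summaries."""
    t, p, df = _pooled_t(mean1, sd1, n1, mean2, sd2, n2)
    return ComparisonResult("parametric", "student_t_pooled", t, p, df)


def compare_two(
    group1: Sequence[float],
    group2: Sequence[float],
    branch: Branch | None = None,
) -> ComparisonResult:
    """Two-group comparison on the requested (or gate-decided) branch.

    Parametric: pooled-variance Student t (df = n1 + n2 - 2).  Rank-based:
    Wilcoxon rank-sum, computed as the equivalent Mann-Whitney U test, exact
    when sample sizes permit.
    """
    a = np.asarray(group1, float)
    b = np.asarray(group2, float)
    gate_p = None
    if branch is None:
        branch, gate_p = _gate([a, b], alpha=0.05)
    if branch == "parametric":
        t, p, df = _pooled_t(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        return ComparisonResult("parametric", "student_t_pooled", t, p, df, gate_p=gate_p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        "rank", "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
        gate_p=gate_p,
    )


def dunn_test(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    p_adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's post hoc test of multiple comparisons after Kruskal-Wallis.

    Pairwise z statistics on mean ranks of the pooled sample with the usual
    tie correction; two-sided p-values adjusted by ``p_adjust``
    (any method accepted by statsmodels' ``multipletests``).
    """
    arrs = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in arrs:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for i, j in itertools.combinations(range(len(arrs)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": labels[i], "group2": labels[j], "statistic": z, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method=p_adjust)[1]
    return table


def compare_many(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    branch: Branch | None = None,
    alpha: float = 0.05,
    dunn_adjust: str = "holm",
) -> ComparisonResult:
    """Multi-group comparison with post hoc pairwise table and letter display.

    Parametric: one-way ANOVA, then Tukey's HSD (family-wise error < alpha).
    Rank-based: Kruskal-Wallis, then Dunn's test with ``dunn_adjust``
    adjustment.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 3:
        raise ValueError("compare_many needs >= 3 groups; use compare_two")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrs))]
    labels = list(labels)
    gate_p = None
    if branch is None:
        branch, gate_p = _gate(arrs, alpha=0.05)

    if branch == "parametric":
        if all(np.ptp(g) == 0 for g in arrs) and len({g[0] for g in arrs}) == 1:
            # identical constant groups: F = 0/0 -> no group effect
            stat_val, p_val = 0.0, 1.0
            k, n_tot = len(arrs), sum(g.size for g in arrs)
            posthoc = pd.DataFrame(
                {
                    "group1": [labels[i] for i, j in itertools.combinations(range(k), 2)],
                    "group2": [labels[j] for i, j in itertools.combinations(range(k), 2)],
                    "statistic": 0.0,
                    "p_adj": 1.0,
                }
            )
            df: tuple[float, float] | None = (k - 1, n_tot - k)
        else:
            f_res = stats.f_oneway(*arrs)
            stat_val, p_val = float(f_res.statistic), float(f_res.pvalue)
            if math.isnan(stat_val):  # zero within-group variance, means differ
                stat_val, p_val = math.inf, 0.0
            k, n_tot = len(arrs), sum(g.size for g in arrs)
            df = (k - 1, n_tot - k)
            hsd = stats.tukey_hsd(*arrs)
            rows = []
            for i, j in itertools.combinations(range(k), 2):
                rows.append(
                    {
                        "group1": labels[i],
                        "group2": labels[j],
                        "statistic": float(hsd.statistic[i, j]),
                        "p_adj": float(hsd.pvalue[i, j]),
                    }
                )
            posthoc = pd.DataFrame(rows)
        test = "anova_tukey_hsd"
    else:
        kw = stats.kruskal(*arrs)
        stat_val, p_val = float(kw.statistic), float(kw.pvalue)
        df = float(len(arrs) - 1)
        posthoc = dunn_test(arrs, labels, p_adjust=dunn_adjust)
        test = "kruskal_dunn"

    letters = compact_letter_display(labels, posthoc, alpha=alpha)
    return ComparisonResult(
        branch, test, stat_val, p_val, df, posthoc, letters, gate_p
    )


def gated_compare(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> ComparisonResult:
    """Full gated procedure: Levene gate, then the matching 2- or k-group test."""
    if len(groups) == 2:
        return compare_two(groups[0], groups[1])
    return compare_many(groups, labels)


def compact_letter_display(
    labels: Sequence[str], posthoc: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Letter codes from an adjusted-p pairwise table.

    Two groups share at least one letter iff their adjusted p >= alpha.
    Letters are the maximal cliques of the "not significantly different"
    graph, ordered by first group membership.
    """
    labels = list(labels)
    n = len(labels)
    idx = {g: i for i, g in enumerate(labels)}
    adj = np.eye(n, dtype=bool)
    for row in posthoc.itertuples(index=False):
        i, j = idx[row.group1], idx[row.group2]
        ok = row.p_adj >= alpha
        adj[i, j] = adj[j, i] = ok

    def is_clique(members: tuple[int, ...]) -> bool:
        return all(adj[a, b] for a, b in itertools.combinations(members, 2))

    if n > 20:
        raise ValueError("letter display supported for <= 20 groups")
    cliques: list[tuple[int, ...]] = []
    for size in range(n, 0, -1):
        for members in itertools.combinations(range(n), size):
            if is_clique(members) and not any(
                set(members) <= set(c) for c in cliques
            ):
                cliques.append(members)
    cliques.sort(key=lambda c: c[0])
    letters_of: dict[str, str] = {g: "" for g in labels}
    for letter_i, members in enumerate(cliques):
        ch = chr(ord("a") + letter_i)
        for m in members:
            letters_of[labels[m]] += ch
    return letters_of
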