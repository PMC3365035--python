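"""Treatment comparisons: omnibus tests, corrected pairwise tests, letters.

Two testing schemes are provided, matching common practice for this kind of
replicate data: one-way ANOVA with Tukey-HSD pairwise comparisons for roughly
normal quantities (percent retention, gamma), and Kruskal-Wallis with a
Tukey-type comparison on average ranks (Nemenyi) for heavily skewed ones
(stemminess).  Each report carries a compact letter display: treatments that
share a letter are NOT significantly different after correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class ComparisonReport:
    """Result of one omnibus test plus corrected pairwise comparisons."""

    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame  # columns: group1, group2, p_adj, significant
    letters: dict
    alpha: float = ALPHA
    degenerate: bool = False

    def significant_pairs(self) -> set[frozenset]:
        return {
            frozenset((r.group1, r.group2))
            for r in self.pairwise.itertuples()
            if r.significant
        }


def _validate(groups: Mapping[str, Sequence[float]]) -> dict:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    clean = {}
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=np.float64)
        if arr.size < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {label!r} contains non-finite values")
        clean[label] = arr
    return clean


def compact_letter_display(
    labels: Sequence[str], significant: set[frozenset]
) -> dict:
    """Assign letters so that groups sharing a letter are not significantly
    different (insert-and-absorb algorithm).  The letter partition depends
    only on the significance relation, not on group order."""
    columns: list[set] = [set(labels)]
    for pair in sorted(significant, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
        # absorb columns contained in another
        columns = [
            col
            for i, col in enumerate(columns)
            if col and not any(col < other for other in columns)
            and columns.index(col) == i  # drop duplicates
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {label: "" for label in labels}
    for i, col in enumerate(sorted(columns, key=lambda c: sorted(c))):
        for label in col:
            letters[label] += alphabet[i % len(alphabet)]
    return {label: "".join(sorted(s)) for label, s in letters.items()}


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA,
    include_pairwise: bool = True,
) -> ComparisonReport:
    """One-way ANOVA followed by Tukey-HSD pairwise comparisons.

    ``include_pairwise=False`` computes only the omnibus test (the pairwise
    stage dominates the cost and does not affect the omnibus p-value), which
    is convenient when screening many datasets.
    """
    clean = _validate(groups)
    labels = list(clean)
    arrays = [clean[k] for k in labels]
    pooled = np.concatenate(arrays)
    degenerate = all(a.var(ddof=1) == 0 for a in arrays)
    if degenerate or np.ptp(pooled) == 0:
        # no within-group variance anywhere: the F statistic is undefined
        pairwise = pd.DataFrame(
            [
                dict(group1=a, group2=b, p_adj=np.nan, significant=False)
                for a, b in combinations(labels, 2)
            ]
        )
        return ComparisonReport(
            test="anova_tukey", statistic=np.nan, pvalue=np.nan,
            pairwise=pairwise, letters=compact_letter_display(labels, set()),
            alpha=alpha, degenerate=True,
        )
    f_stat, f_p = stats.f_oneway(*arrays)
    if not include_pairwise:
        return ComparisonReport(
            test="anova_tukey", statistic=float(f_stat), pvalue=float(f_p),
            pairwise=pd.DataFrame(
                columns=["group1", "group2", "p_adj", "significant"]
            ),
            letters={}, alpha=alpha,
        )
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        p_adj = float(hsd.pvalue[i, j])
        rows.append(
            dict(
                group1=labels[i],
                group2=labels[j],
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    pairwise = pd.DataFrame(rows)
    sig = {
        frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if r.significant
    }
    return ComparisonReport(
        test="anova_tukey",
        statistic=float(f_stat),
        pvalue=float(f_p),
        pairwise=pairwise,
        letters=compact_letter_display(labels, sig),
        alpha=alpha,
    )


def kruskal_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = ALPHA,
    include_pairwise: bool = True,
) -> ComparisonReport:
    """Kruskal-Wallis omnibus test with Tukey-type pairwise rank comparisons.

    Pairwise comparisons follow the Nemenyi procedure: differences in average
    pooled rank are referred to the studentized-range distribution, i.e. a
    Tukey-HSD-style correction applied to ranks.  ``include_pairwise=False``
    computes only the omnibus test.
    """
    clean = _validate(groups)
    labels = list(clean)
    arrays = [clean[k] for k in labels]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairwise = pd.DataFrame(
            [
                dict(group1=a, group2=b, p_adj=np.nan, significant=False)
                for a, b in combinations(labels, 2)
            ]
        )
        return ComparisonReport(
            test="kruskal_tukey", statistic=np.nan, pvalue=np.nan,
            pairwise=pairwise, letters=compact_letter_display(labels, set()),
            alpha=alpha, degenerate=True,
        )
    h_stat, h_p = stats.kruskal(*arrays)
    if not include_pairwise:
        return ComparisonReport(
            test="kruskal_tukey", statistic=float(h_stat), pvalue=float(h_p),
            pairwise=pd.DataFrame(
                columns=["group1", "group2", "p_adj", "significant"]
            ),
            letters={}, alpha=alpha,
        )
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    k_groups = len(labels)
    mean_ranks, sizes = [], []
    start = 0
    for arr in arrays:
        mean_ranks.append(ranks[start : start + arr.size].mean())
        sizes.append(arr.size)
        start += arr.size
    rows = []
    for i, j in combinations(range(k_groups), 2):
        se = np.sqrt(
            n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k_groups, np.inf))
        p_adj = min(max(p_adj, 0.0), 1.0)
        rows.append(
            dict(
                group1=labels[i],
                group2=labels[j],
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    pairwise = pd.DataFrame(rows)
    sig = {
        frozenset((r.group1, r.group2)) for r in pairwise.itertuples() if r.significant
    }
    return ComparisonReport(
        test="kruskal_tukey",
        statistic=float(h_stat),
        pvalue=float(h_p),
        pairwise=pairwise,
        letters=compact_letter_display(labels, sig),
        alpha=alpha,
    )
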