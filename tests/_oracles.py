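"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package internals: node ages are
re-derived by explicit enumeration of surviving descent lines, and gamma by
sweeping time in unit steps to re-count lineages.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from phyloerosion.genealogy import GenealogyLog


def brute_force_node_ages(log: GenealogyLog, sample_time: float) -> Counter:
    """Multiset of branching-node ages (with multifurcation multiplicity) by
    direct enumeration: an event at age s on genotype g's timeline yields
    k - 1 splits, where k counts the surviving same-age child lines plus g's
    own surviving continuation (g extant, or a later child event that leads
    to extant descendants)."""
    n = len(log)
    extant = set(int(i) for i in log.extant_at(sample_time))

    children: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(1, n):
        children[log.parent[i]].append(i)

    def leads_to_extant(g: int) -> bool:
        stack = [g]
        while stack:
            x = stack.pop()
            if x in extant:
                return True
            stack.extend(children[x])
        return False

    ages: Counter = Counter()
    for g in range(n):
        if not leads_to_extant(g):
            continue
        surviving = [c for c in children[g] if leads_to_extant(c)]
        event_ages = sorted({log.origin[c] for c in surviving})
        for s in event_ages:
            m = sum(1 for c in surviving if log.origin[c] == s)
            cont = g in extant or any(log.origin[c] > s for c in surviving)
            k = m + (1 if cont else 0)
            if k >= 2:
                ages[float(s)] += k - 1
    return ages


def sweep_gamma(branching_ages, sample_time) -> float:
    """Gamma re-derived by unit-step time sweeping (requires integer ages).

    Lineage counts are re-counted at every unit step, internode intervals are
    tallied from those counts, and the statistic is evaluated with explicit
    loops, independent of the package's vectorized path.
    """
    ages = sorted(float(a) for a in branching_ages)
    n = len(ages) + 1
    assert n >= 3
    root = int(ages[0])
    end = int(sample_time)
    g = {k: 0 for k in range(2, n + 1)}
    for t in range(root, end):
        lineages = 1 + sum(1 for a in ages if a <= t)
        g[lineages] += 1
    big_t = sum(k * gk for k, gk in g.items())
    partial = 0.0
    acc = []
    for k in range(2, n + 1):
        partial += k * g[k]
        acc.append(partial)
    mean_a = sum(acc[:-1]) / (n - 2)
    return (mean_a - big_t / 2.0) / (big_t * np.sqrt(1.0 / (12.0 * (n - 2))))
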