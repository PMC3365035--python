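"""Tree-shape statistics: LTT, Pybus-Harvey gamma, stemminess, root gaps.

All statistics operate on ultrametric trees whose ages are in updates, with
the "present" taken to be the sampling time.  Multifurcations are treated as
simultaneous binary splits separated by zero-length internode intervals, so a
node with *m* children contributes *m - 1* branching events at its age and the
``sum(k * g_k)`` accounting of the gamma statistic needs no arbitrary
resolution of polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedStatisticError
from .phylogeny import PhyloTree


@dataclass
class LTTSeries:
    """Lineage-through-time data of one ultrametric tree.

    ``branching_ages`` are the sorted internal-node ages ``t_2 <= ... <= t_n``
    (one entry per binary split); during the internode interval
    ``g_k = t_{k+1} - t_k`` exactly *k* lineages exist, with
    ``t_{n+1} = sample_time``.
    """

    branching_ages: np.ndarray
    sample_time: float
    n: int

    def __post_init__(self) -> None:
        self.branching_ages = np.sort(
            np.asarray(self.branching_ages, dtype=np.float64)
        )
        if self.branching_ages.size != self.n - 1:
            raise ValueError(
                f"expected {self.n - 1} branching ages for n={self.n} tips, "
                f"got {self.branching_ages.size}"
            )
        if self.branching_ages.size and self.branching_ages[-1] > self.sample_time:
            raise ValueError("branching after the sampling time")

    @property
    def root_age(self) -> float:
        return float(self.branching_ages[0])

    def intervals(self) -> np.ndarray:
        """Internode intervals ``g_k`` for k = 2..n (all >= 0)."""
        return np.diff(np.append(self.branching_ages, self.sample_time))


def ltt(tree: PhyloTree) -> LTTSeries:
    """Extract LTT data: node ages with multifurcation multiplicity m - 1."""
    n = tree.n_tips
    if n < 2:
        raise UndefinedStatisticError("LTT needs at least 2 tips")
    return LTTSeries(
        branching_ages=tree.node_ages(multiplicity=True),
        sample_time=tree.sample_time,
        n=n,
    )


def pybus_harvey_gamma(data) -> float:
    """Pybus-Harvey gamma statistic of an ultrametric tree.

    With ``T = sum_{k=2}^{n} k * g_k`` and partial sums
    ``A_i = sum_{k=2}^{i} k * g_k``::

        gamma = [ mean_{i=2..n-1}(A_i) - T/2 ] / [ T * sqrt(1 / (12 (n-2))) ]

    Negative values indicate branching concentrated towards the root,
    positive values towards the tips.  Under a constant-rate pure-birth
    process gamma is asymptotically standard normal.

    Accepts an :class:`LTTSeries` or a :class:`PhyloTree`.  Undefined for
    fewer than 3 tips or for a zero total ``T``.
    """
    series = data if isinstance(data, LTTSeries) else ltt(data)
    n = series.n
    if n < 3:
        raise UndefinedStatisticError(f"gamma undefined for n={n} tips (< 3)")
    g = series.intervals()
    k = np.arange(2, n + 1, dtype=np.float64)
    kg = k * g
    big_t = kg.sum()
    if big_t <= 0:
        raise UndefinedStatisticError("gamma undefined: zero tree height")
    partial = np.cumsum(kg)  # partial[i-2] = A_i
    mean_a = partial[:-1].sum() / (n - 2)
    return float((mean_a - big_t / 2.0) / (big_t * np.sqrt(1.0 / (12.0 * (n - 2)))))


@dataclass
class StemminessResult:
    """Noncumulative stemminess of one tree.

    ``value`` is the arithmetic mean of the per-node scores over the internal
    non-root nodes that were included; ``n_skipped`` counts nodes excluded
    because their score was undefined (zero-length denominators).
    """

    value: float
    variant: str
    n_internal_nodes: int
    n_skipped: int = 0


NCS_VARIANTS = ("rohlf1990", "inverse-ratio")


def ncs(tree: PhyloTree, variant: str = "rohlf1990") -> StemminessResult:
    """Noncumulative stemminess: per-node stem-to-local-branch ratios.

    For an internal non-root node *j* with stem length ``l_j`` (to its
    parent) and immediate child branch lengths ``{l_c}``:

    * ``rohlf1990``:  ``s_j = l_j / (l_j + sum(l_c))`` -- bounded in [0, 1];
      small values mean long branches radiating just below the node.
    * ``inverse-ratio``:  ``s'_j = sum(l_c) / l_j`` -- unbounded above;
      values above 1 indicate short stems (branching packed near the root),
      values below 1 long stems.  Nodes with ``l_j = 0`` are skipped (and
      counted) rather than treated as infinite.

    The tree value is the mean over included nodes; a tree with no internal
    non-root node (2-tip or star-from-root) has no defined NCS.
    """
    if variant not in NCS_VARIANTS:
        raise ValueError(f"unknown NCS variant {variant!r}; use {NCS_VARIANTS}")
    scores: list[float] = []
    skipped = 0
    stack = [(tree.root, None)]
    while stack:
        node, parent_age = stack.pop()
        if not node.is_tip:
            stack.extend((c, node.age) for c in node.children)
        if node.is_tip or parent_age is None:
            continue  # tips and the root itself carry no score
        stem = node.age - parent_age
        child_sum = sum(c.age - node.age for c in node.children)
        if variant == "rohlf1990":
            denom = stem + child_sum
            if denom <= 0:
                skipped += 1
                continue
            scores.append(stem / denom)
        else:
            if stem <= 0:
                skipped += 1
                continue
            scores.append(child_sum / stem)
    if not scores:
        raise UndefinedStatisticError(
            "NCS undefined: no internal non-root node with a usable score"
        )
    return StemminessResult(
        value=float(np.mean(scores)),
        variant=variant,
        n_internal_nodes=len(scores),
        n_skipped=skipped,
    )


def root_age(tree: PhyloTree) -> float:
    """Age of the deepest branching node (the MRCA of the extant sample)."""
    return tree.root_age


def root_gap_distances(tree: PhyloTree):
    """Distances from the root to the first and second next-oldest nodes.

    Returns ``(d1, d2)`` in updates; a missing node (fewer than 2 or 3
    branching events) yields ``None`` in its place.  Multifurcations count as
    co-occurring splits, so a multifurcating root gives ``d1 = 0``.
    """
    ages = tree.node_ages(multiplicity=True)
    d1 = float(ages[1] - ages[0]) if ages.size >= 2 else None
    d2 = float(ages[2] - ages[0]) if ages.size >= 3 else None
    return d1, d2


def yule_ltt(
    n_tips: int, rng: np.random.Generator, birth_rate: float = 1.0
) -> LTTSeries:
    """LTT of a pure-birth (Yule) tree: while k lineages exist the next
    branching waits an Exp(k * birth_rate) time.  Used for calibrating the
    gamma statistic, whose null distribution under this process is standard
    normal in the large-tree limit."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    k = np.arange(2, n_tips + 1)
    gaps = rng.exponential(1.0 / (k * birth_rate))
    times = np.concatenate([[0.0], np.cumsum(gaps)])
    return LTTSeries(
        branching_ages=times[:-1], sample_time=float(times[-1]), n=n_tips
    )
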