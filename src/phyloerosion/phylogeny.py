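"""From genealogy logs to ultrametric phylogenies of extant genotypes.

The genealogy records every genotype ever created; the "molecular" phylogeny
keeps only genotypes extant at the sampling time as tips.  Every child-origin
event along an ancestor's timeline is a *potential* branching node; it becomes
a real internal node only if at least two lines of descent from it survive to
the sampling time (counting the ancestor's own continuation when the ancestor
itself is extant or leads to extant descendants).  All other events collapse
into branch length, which is why these trees carry long stems.  Node ages are
branching times in updates; tips all sit at the sampling time, so the tree is
ultrametric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import dendropy
import numpy as np

from .errors import DegenerateTreeError, NonUltrametricError
from .genealogy import GenealogyLog


class PhyloNode:
    """Node of an ultrametric tree: ``age`` in updates, ordered children.

    Tips carry the genotype id in ``label`` and have ``age`` equal to the
    sampling time.  Internal nodes record in ``host`` the id of the ancestral
    genotype on whose timeline the branching event occurred (used for
    root-identity matching between trees of the same replicate).
    """

    __slots__ = ("age", "children", "label", "host")

    def __init__(self, age: float, children: list | None = None,
                 label: str | None = None, host: str | None = None) -> None:
        self.age = age
        self.children: list[PhyloNode] = children if children is not None else []
        self.label = label
        self.host = host

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.label if self.is_tip else f"node/{len(self.children)}"
        return f"<PhyloNode {kind} age={self.age}>"


@dataclass
class PhyloTree:
    """Rooted ultrametric tree of extant genotypes, ages in updates.

    ``origin`` is the time the root lineage started (the founder's origin,
    normally 0); the root's stem length is ``root_age - origin``.
    """

    root: PhyloNode
    sample_time: float
    origin: float = 0.0

    @property
    def root_age(self) -> float:
        return self.root.age

    def iter_nodes(self) -> Iterator[PhyloNode]:
        """Preorder traversal (iterative: trees can be deep)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[PhyloNode]:
        return [n for n in self.iter_nodes() if n.is_tip]

    def internal_nodes(self) -> list[PhyloNode]:
        return [n for n in self.iter_nodes() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.iter_nodes() if n.is_tip)

    def node_ages(self, multiplicity: bool = True) -> np.ndarray:
        """Sorted internal-node ages; a node with m children counts m-1 times
        when ``multiplicity`` is set (the multifurcation = simultaneous-splits
        convention used by the LTT and root-gap statistics)."""
        ages: list[float] = []
        for node in self.internal_nodes():
            reps = len(node.children) - 1 if multiplicity else 1
            ages.extend([node.age] * reps)
        return np.sort(np.asarray(ages, dtype=np.float64))


def _sort_children(root: PhyloNode) -> None:
    """Order children by smallest descendant tip label, for reproducible
    serialization (genotype-id lexicographic tie-break)."""
    order: dict[int, str] = {}
    for node in _postorder(root):
        if node.is_tip:
            order[id(node)] = node.label or ""
        else:
            node.children.sort(key=lambda c: order[id(c)])
            order[id(node)] = order[id(node.children[0])]


def _postorder(root: PhyloNode) -> Iterator[PhyloNode]:
    stack: list[tuple[PhyloNode, bool]] = [(root, False)]
    while stack:
        node, seen = stack.pop()
        if seen or node.is_tip:
            yield node
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in reversed(node.children))


def build_tree(
    log: GenealogyLog, sample_time: float, extant=None
) -> PhyloTree:
    """Prune the genealogy to the ultrametric phylogeny of extant genotypes.

    Parameters
    ----------
    log
        Full genotype genealogy (single founder root).
    sample_time
        Time of sampling, in updates; tips are genotypes extant then.
    extant
        Optional explicit array of genotype record indices to use as tips
        (e.g. the survivor census right after a pulse cull); defaults to every
        genotype extant at ``sample_time`` according to the log.

    Raises
    ------
    DegenerateTreeError
        If fewer than two genotypes are extant (no MRCA exists).
    """
    parent, origin, _ = log.arrays()
    if extant is None:
        extant = log.extant_at(sample_time)
    extant = np.asarray(extant, dtype=np.int64)
    if extant.size < 2:
        raise DegenerateTreeError(
            f"{extant.size} extant genotype(s) at t={sample_time}; need >= 2"
        )
    if (origin[extant] > sample_time).any():
        raise ValueError("extant genotype originates after sample_time")

    n = len(log)
    has_desc = np.zeros(n, dtype=bool)
    has_desc[extant] = True
    extant_set = set(int(i) for i in extant)
    for i in range(n - 1, 0, -1):  # record order is temporal order
        if has_desc[i]:
            has_desc[parent[i]] = True
    if not has_desc[0]:
        raise ValueError("extant genotypes do not descend from the founder")

    # Surviving child events per ancestor, already in ascending origin order.
    events: dict[int, list[int]] = {}
    for i in range(1, n):
        if has_desc[i]:
            events.setdefault(int(parent[i]), []).append(i)

    subtree: dict[int, PhyloNode] = {}
    for i in range(n - 1, -1, -1):
        if not has_desc[i]:
            continue
        gid = log.label(i)
        cur = (
            PhyloNode(age=float(sample_time), label=gid)
            if i in extant_set
            else None
        )
        for c in reversed(events.get(i, ())):
            child_sub = subtree.pop(c)
            age = float(origin[c])
            if cur is None:
                cur = child_sub  # single surviving line: event collapses
            elif cur.host == gid and not cur.is_tip and cur.age == age:
                cur.children.append(child_sub)  # simultaneous event: multifurcate
            else:
                cur = PhyloNode(age=age, children=[cur, child_sub], host=gid)
        subtree[i] = cur
    root = subtree[0]
    assert root is not None and not root.is_tip
    _sort_children(root)
    return PhyloTree(root=root, sample_time=float(sample_time),
                     origin=float(origin[0]))


# ---------------------------------------------------------------------------
# newick I/O (dendropy does the parsing/serialization)


def to_newick(tree: PhyloTree, internal_labels: bool = False) -> str:
    """Serialize to newick with branch lengths in updates.

    The root edge length is ``root_age - origin`` so that node ages survive a
    round trip through :func:`from_newick`.
    """
    dtree = dendropy.Tree()
    mapping = {id(tree.root): dtree.seed_node}
    dtree.seed_node.edge.length = tree.root_age - tree.origin
    for node in tree.iter_nodes():
        dnode = mapping[id(node)]
        if node.is_tip:
            dnode.taxon = dtree.taxon_namespace.new_taxon(label=node.label)
        elif internal_labels and node.host is not None:
            dnode.label = node.host
        for child in node.children:
            dchild = dnode.new_child(edge_length=child.age - node.age)
            mapping[id(child)] = dchild
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip()


def from_newick(text: str, ultrametric_tol: float = 1e-6) -> PhyloTree:
    """Parse a newick string (branch lengths mandatory) into a PhyloTree.

    Ages are recovered by summing stem lengths from the root; the root edge
    length, when present, offsets the root age from time 0.  Inputs whose tip
    depths differ by more than ``ultrametric_tol`` times the tree height are
    rejected, since every downstream statistic assumes ultrametry.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)
    seed = dtree.seed_node
    root_age = seed.edge.length if seed.edge.length is not None else 0.0

    root = PhyloNode(age=float(root_age))
    stack = [(seed, root)]
    tip_ages = []
    while stack:
        dnode, node = stack.pop()
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon else dnode.label
            tip_ages.append(node.age)
        for dchild in dnode.child_nodes():
            length = dchild.edge.length
            if length is None:
                raise ValueError("newick input must carry branch lengths")
            child = PhyloNode(age=node.age + float(length))
            node.children.append(child)
            stack.append((dchild, child))
    if not tip_ages:
        raise ValueError("empty tree")
    sample_time = max(tip_ages)
    tol = ultrametric_tol * max(sample_time, 1.0)
    if max(tip_ages) - min(tip_ages) > tol:
        raise NonUltrametricError(
            f"tip depths span {max(tip_ages) - min(tip_ages):g} updates "
            f"(tolerance {tol:g}); metrics assume ultrametric trees"
        )
    for node in PhyloTree(root, sample_time).tips():
        node.age = float(sample_time)  # absorb sub-tolerance rounding
    return PhyloTree(root=root, sample_time=float(sample_time), origin=0.0)


def prune_nodes_after(ages, cutoff: float) -> np.ndarray:
    """Keep only node ages <= cutoff (discard nodes originating after the
    start of the extinction event, for comparisons on common temporal
    support)."""
    ages = np.asarray(ages, dtype=np.float64)
    return ages[ages <= cutoff]
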