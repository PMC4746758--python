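"""Unrooted phylogenetic trees: Newick I/O, bipartition algebra, backbone
constraints, topology enumeration, NNI search, bootstrap support and
gene-tree conflict scanning.

Trees are stored rooted at an arbitrary internal node purely as a traversal
convenience; all semantics (splits, constraint display, NNI) are those of the
underlying unrooted tree.  A *backbone constraint* is a possibly
multifurcating tree on a subset of the taxa; a binary tree displays it iff
every non-trivial split of the constraint appears among the tree's splits
after restriction to the constraint's taxa (polytomies impose nothing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DataError, UsageError

__all__ = [
    "Node", "PhyloTree", "Bipartition", "parse_newick", "bipartitions",
    "displays", "enumerate_topologies", "nni_neighbors", "random_addition_tree",
    "monophyly_constraint", "conflict_scan", "search_ml", "bootstrap_support",
    "splits_compatible",
]


class Node:
    """Tree node; ``length`` is the length of the edge to the parent."""

    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support = support

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree held in a rooted representation (root = internal node)."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        if len(self.root.children) not in (3,) and self.n_leaves > 2:
            return False
        return all(len(n.children) == 2 for n in self.preorder()
                   if n is not self.root and not n.is_leaf)

    # -- copying -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for ch in node.children:
                new.add(rec(ch))
            return new
        return PhyloTree(rec(self.root))

    # -- Newick ------------------------------------------------------------
    def newick(self, lengths: bool = True, supports: bool = True) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
                if supports and node.support is not None:
                    s += f"{node.support:.12g}"
                elif node.label:
                    s += node.label
            if lengths and node.length is not None and node is not self.root:
                s += f":{node.length:.12g}"
            return s
        return rec(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only Newick with children sorted by smallest leaf label;
        canonical across re-rootings of the same unrooted tree (the traversal
        root is first moved to the internal node adjacent to the globally
        smallest leaf label)."""
        def minleaf(node: Node) -> str:
            if node.is_leaf:
                return node.label
            return min(minleaf(c) for c in node.children)

        tree = self.copy()
        target = min(tree.leaf_labels())
        for n in tree.preorder():
            if n.is_leaf and n.label == target and n.parent is not None:
                tree = _reroot_at(tree, n.parent)
                break

        def rec(node: Node) -> str:
            if node.is_leaf:
                return node.label
            parts = sorted(rec(c) for c in node.children)
            return "(" + ",".join(parts) + ")"
        return rec(tree.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.newick()!r})"


def _reroot_at(tree: PhyloTree, node: Node) -> PhyloTree:
    """Return a copy of the unrooted tree re-rooted (for traversal) at
    the internal node corresponding to ``node``'s position."""
    if node is tree.root:
        return tree
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    # path = [node, ..., root]; flip each edge, moving its attributes with it
    for i in range(len(path) - 1, 0, -1):
        upper, lower = path[i], path[i - 1]
        upper.children.remove(lower)
        lower.children.append(upper)
        upper.parent = lower
        upper.length = lower.length
        upper.support = lower.support
    node.parent = None
    node.length = None
    node.support = None
    return PhyloTree(node)


# ---------------------------------------------------------------------------
# Newick parsing (dendropy-backed)

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    Numeric internal-node labels are read as bootstrap/support values.
    Rooted (bifurcating-at-root) strings are unrooted on input.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise DataError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            lab = dnode.label
            if lab is not None:
                try:
                    node.support = float(lab)
                except ValueError:
                    node.label = lab
            for ch in dnode.child_nodes():
                node.add(convert(ch))
        return node

    root = convert(dtree.seed_node)
    tree = PhyloTree(root)
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        raise DataError("duplicate leaf labels in Newick input")
    _unroot(tree)
    return tree


def _unroot(tree: PhyloTree) -> None:
    """Collapse a degree-2 root so the traversal root is a real unrooted node."""
    root = tree.root
    while len(root.children) == 2 and any(not c.is_leaf for c in root.children):
        internal = next(c for c in root.children if not c.is_leaf)
        other = next(c for c in root.children if c is not internal)
        # merge: internal becomes the new root; other hangs off it with the
        # combined edge length
        root.children.remove(internal)
        if other.length is not None or internal.length is not None:
            other.length = (other.length or 0.0) + (internal.length or 0.0)
        for ch in list(root.children):
            internal.add(ch)
        internal.parent = None
        internal.length = None
        tree.root = internal
        root = internal


# ---------------------------------------------------------------------------
# Bipartitions

@dataclass(frozen=True)
class Bipartition:
    """A split of a taxon set into two blocks, with optional support."""

    block_a: frozenset
    block_b: frozenset
    support: float | None = None

    @property
    def key(self) -> frozenset:
        return frozenset((self.block_a, self.block_b))

    @property
    def taxa(self) -> frozenset:
        return self.block_a | self.block_b

    def restricted(self, taxa) -> "Bipartition | None":
        """Restrict to a taxon subset; None if the result is trivial."""
        taxa = frozenset(taxa)
        a, b = self.block_a & taxa, self.block_b & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, b, self.support)

    def compatible(self, other: "Bipartition") -> bool:
        return splits_compatible(self, other)

    def __repr__(self) -> str:  # pragma: no cover
        a = ",".join(sorted(self.block_a))
        b = ",".join(sorted(self.block_b))
        if sorted(self.block_a)[0] > sorted(self.block_b)[0]:
            a, b = b, a
        return f"{{{a}}}|{{{b}}}"


def splits_compatible(s1: Bipartition, s2: Bipartition) -> bool:
    """Two splits are compatible iff at least one of the four pairwise block
    intersections is empty."""
    return (not (s1.block_a & s2.block_a) or not (s1.block_a & s2.block_b)
            or not (s1.block_b & s2.block_a) or not (s1.block_b & s2.block_b))


def bipartitions(tree: PhyloTree, restrict_to=None) -> list[Bipartition]:
    """Non-trivial splits induced by the internal edges of a tree, optionally
    restricted to a taxon subset (with degree-2 suppression implied).

    Edges whose restricted splits coincide are merged; the highest attached
    support is kept.
    """
    all_taxa = frozenset(tree.leaf_labels())
    taxa = all_taxa if restrict_to is None else frozenset(restrict_to) & all_taxa
    if len(taxa) < 4:
        return []
    below: dict[int, frozenset] = {}
    out: dict[frozenset, Bipartition] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        bl = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = bl
        if node.parent is None:
            continue
        a = bl & taxa
        b = taxa - a
        if len(a) < 2 or len(b) < 2:
            continue
        bp = Bipartition(a, b, node.support)
        prev = out.get(bp.key)
        if prev is None or (bp.support or -1) > (prev.support if prev.support is not None else -1):
            out[bp.key] = bp
    return list(out.values())


def displays(tree: PhyloTree, constraint: PhyloTree) -> bool:
    """True iff ``tree`` displays the (possibly multifurcating, possibly
    partial-taxon) backbone ``constraint``."""
    ctaxa = frozenset(constraint.leaf_labels())
    if not ctaxa <= frozenset(tree.leaf_labels()):
        raise UsageError("constraint taxa are not a subset of the tree's taxa")
    need = bipartitions(constraint)
    if not need:
        return True
    have = {bp.key for bp in bipartitions(tree, restrict_to=ctaxa)}
    return all(bp.key in have for bp in need)


def monophyly_constraint(group, all_taxa) -> PhyloTree:
    """Backbone constraint forcing ``group`` to be monophyletic within
    ``all_taxa`` (single non-trivial split; everything else unresolved)."""
    group = list(dict.fromkeys(group))
    rest = [t for t in all_taxa if t not in set(group)]
    if len(group) < 2 or len(rest) < 2:
        raise UsageError("monophyly constraint needs >= 2 taxa on each side")
    root = Node()
    inner = root.add(Node())
    for t in group:
        inner.add(Node(label=t))
    for t in rest:
        root.add(Node(label=t))
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Topology generation

MAX_EXHAUSTIVE_TAXA = 9


def _edges(tree: PhyloTree) -> list[Node]:
    """All edges, each identified by its child node, in preorder."""
    return [n for n in tree.preorder() if n.parent is not None]


def enumerate_topologies(taxa) -> "itertools.chain":
    """Yield every unrooted binary topology on ``taxa`` exactly once
    (unit branch lengths).  Guarded to n <= 9 since there are (2n-5)!! trees."""
    taxa = list(taxa)
    n = len(taxa)
    if n < 3:
        raise UsageError("need at least 3 taxa")
    if n > MAX_EXHAUSTIVE_TAXA:
        raise UsageError(
            f"{n} taxa give (2n-5)!! topologies; use the NNI search instead")

    def build(k: int):
        if k == 3:
            root = Node()
            for t in taxa[:3]:
                root.add(Node(label=t, length=1.0))
            yield PhyloTree(root)
            return
        for tree in build(k - 1):
            edges = _edges(tree)
            for i in range(len(edges)):
                new = tree.copy()
                target = _edges(new)[i]
                _insert_leaf_on_edge(new, target, taxa[k - 1])
                yield new

    return build(n)


def _insert_leaf_on_edge(tree: PhyloTree, edge_child: Node, label: str) -> None:
    parent = edge_child.parent
    mid = Node(length=1.0)
    parent.children[parent.children.index(edge_child)] = mid
    mid.parent = parent
    mid.add(edge_child)
    mid.add(Node(label=label, length=1.0))


def random_addition_tree(taxa, rng: np.random.Generator,
                         branch_length: float = 0.1) -> PhyloTree:
    """Random stepwise-addition starting tree."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise UsageError("need at least 3 taxa")
    order = list(rng.permutation(len(taxa)))
    root = Node()
    for i in order[:3]:
        root.add(Node(label=taxa[i], length=branch_length))
    tree = PhyloTree(root)
    for i in order[3:]:
        edges = _edges(tree)
        target = edges[int(rng.integers(len(edges)))]
        _insert_leaf_on_edge(tree, target, taxa[i])
        target.length = branch_length
        target.parent.length = branch_length
        target.parent.children[1].length = branch_length
    return tree


def _internal_edges(tree: PhyloTree) -> list[Node]:
    """Internal edges (child node internal, non-root), preorder-deterministic."""
    return [n for n in tree.preorder()
            if n.parent is not None and not n.is_leaf]


def nni_neighbors(tree: PhyloTree) -> list[PhyloTree]:
    """The 2(n-3) nearest-neighbour-interchange neighbours of a binary tree.

    Branch lengths travel with their subtrees.
    """
    if not tree.is_binary():
        raise UsageError("NNI requires a binary tree")
    out = []
    n_int = len(_internal_edges(tree))
    for k in range(n_int):
        for which in (0, 1):
            new = tree.copy()
            c = _internal_edges(new)[k]
            p = c.parent
            # one subtree on the parent side of the edge: a sibling of c
            s = next(ch for ch in p.children if ch is not c)
            a = c.children[which]
            # swap a <-> s
            c.children[c.children.index(a)] = s
            p.children[p.children.index(s)] = a
            a.parent, s.parent = p, c
            out.append(new)
    return out


# ---------------------------------------------------------------------------
# ML tree search, bootstrap, conflict scanning
# (imported lazily to keep the tree algebra importable on its own)

def search_ml(patterns, model_init, constraint: PhyloTree | None = None,
              strategy: str = "exhaustive", n_starts: int = 5,
              seed: int | None = None, tol: float = 1e-6,
              refit_model: bool = True):
    """Maximum-likelihood tree search; see :mod:`phylosowh.search`."""
    from . import search as _search
    return _search.search_ml(patterns, model_init, constraint=constraint,
                             strategy=strategy, n_starts=n_starts, seed=seed,
                             tol=tol, refit_model=refit_model)


def bootstrap_support(patterns, model, base_tree: PhyloTree, B: int = 1000,
                      seed: int | None = None, strategy: str = "nni",
                      n_starts: int = 1):
    """Nonparametric bootstrap supports; see :mod:`phylosowh.search`."""
    from . import search as _search
    return _search.bootstrap_support(patterns, model, base_tree, B=B,
                                     seed=seed, strategy=strategy,
                                     n_starts=n_starts)


def conflict_scan(tree_a: PhyloTree, tree_b: PhyloTree, cutoff: float = 70.0):
    """Compat-style conflict scan between two support-annotated trees.

    Both trees are restricted to their shared taxa; every pair of mutually
    incompatible splits whose supports both reach ``cutoff`` is reported.
    The scan is symmetric in its arguments (up to pair ordering).
    """
    shared = frozenset(tree_a.leaf_labels()) & frozenset(tree_b.leaf_labels())
    if len(shared) < 4:
        import warnings
        warnings.warn("fewer than 4 shared taxa; conflict scan is empty")
        return []
    sa = [bp for bp in bipartitions(tree_a, restrict_to=shared)
          if bp.support is not None and bp.support >= cutoff]
    sb = [bp for bp in bipartitions(tree_b, restrict_to=shared)
          if bp.support is not None and bp.support >= cutoff]
    out = []
    for x in sa:
        for y in sb:
            if not splits_compatible(x, y):
                out.append((x, y))
    return out
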