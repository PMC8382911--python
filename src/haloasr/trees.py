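"""Rooted trees with branch lengths, dated (ultrametric) species trees, and rooting.

The package keeps its own lightweight node/tree classes so that every
algorithm (pruning likelihood, reconciliation DP, simulators) can attach the
bookkeeping it needs; Newick text goes through dendropy on the way in.
Branch lengths are expected replacements per site unless a tree is explicitly
in time units (ages).
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "Node",
    "Tree",
    "DatedSpeciesTree",
    "midpoint_root",
    "robinson_foulds",
]


class TreeError(ValueError):
    pass


class Node:
    """A node of a rooted tree. ``length`` is the branch to the parent (None at the root)."""

    __slots__ = ("label", "length", "parent", "children", "age")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.age: Optional[float] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length})"


class Tree:
    """Rooted tree; internal nodes binary (the root of an unrooted NJ tree may be trifurcating)."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise TreeError(f"no node labelled {label!r}")

    # -- invariants --------------------------------------------------------
    def validate(self, allow_root_trifurcation: bool = False) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("leaf labels are not unique")
        if any(not lab for lab in labels):
            raise TreeError("empty leaf label")
        for n in self.postorder():
            if n.is_leaf:
                continue
            k = len(n.children)
            ok = k == 2 or (allow_root_trifurcation and n is self.root and k == 3)
            if not ok:
                raise TreeError(f"internal node with {k} children")
            if n is not self.root and n.length is not None and n.length < 0:
                raise TreeError("negative branch length")

    # -- copy / relabel ----------------------------------------------------
    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.age = n.age
            for c in n.children:
                m.add_child(rec(c))
            return m

        return Tree(rec(self.root))

    def label_internal(self, prefix: str = "anc") -> None:
        """Assign deterministic labels anc0, anc1, ... to unlabelled internal nodes (postorder)."""
        i = 0
        for n in self.postorder():
            if not n.is_leaf and not n.label:
                n.label = f"{prefix}{i}"
            if not n.is_leaf:
                i += 1

    # -- clades / distances -------------------------------------------------
    def clades(self) -> dict[Node, frozenset]:
        out: dict[Node, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                out[n] = frozenset([n.label])
            else:
                out[n] = frozenset().union(*(out[c] for c in n.children))
        return out

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (missing branch lengths count as 0)."""
        d: dict[Node, float] = {self.root: 0.0}
        for n in self.preorder():
            if n is self.root:
                continue
            d[n] = d[n.parent] + (n.length or 0.0)
        return d

    # -- newick ------------------------------------------------------------
    def to_newick(self, lengths: bool = True, fmt: str = "%.10g") -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                s = n.label or ""
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")" + (n.label or "")
            if lengths and n.length is not None:
                s += ":" + (fmt % n.length)
            return s

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

        def rec(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label, dnode.edge.length)
            for c in dnode.child_nodes():
                node.add_child(rec(c))
            return node

        return cls(rec(dtree.seed_node))


class DatedSpeciesTree:
    """Ultrametric rooted species tree: leaves at age 0, parent strictly older than child.

    Ages are derived from branch lengths (time units) if not already present
    on the nodes.
    """

    def __init__(self, tree: Tree, tol: float = 1e-9):
        tree.validate()
        self.tree = tree
        depths = tree.depths()
        height = max(depths[lf] for lf in tree.leaves())
        for n in tree.postorder():
            if n.age is None:
                n.age = height - depths[n]
        for lf in tree.leaves():
            if abs(lf.age) > tol * max(height, 1.0):
                raise TreeError("species tree is not ultrametric")
            lf.age = 0.0
        ages = []
        for n in tree.postorder():
            if n.is_leaf:
                continue
            for c in n.children:
                if n.age <= c.age:
                    raise TreeError("parent age not greater than child age")
            ages.append(n.age)
        if len(set(ages)) != len(ages):
            raise TreeError("tied internal node ages; jitter the ages")

    @property
    def root(self) -> Node:
        return self.tree.root

    def internal_ages(self) -> list[float]:
        return sorted(n.age for n in self.tree.internal_nodes())

    def to_newick(self) -> str:
        return self.tree.to_newick()

    @classmethod
    def from_newick(cls, text: str) -> "DatedSpeciesTree":
        return cls(Tree.from_newick(text))


# ---------------------------------------------------------------------------
# midpoint rooting


def _unrooted_edges(tree: Tree):
    """Edge list of the unrooted version: (a, b, length); the root's two incident
    edges are merged into one when the root is binary."""
    edges = []
    root = tree.root
    for n in tree.preorder():
        if n is root:
            continue
        if n.parent is root and len(root.children) == 2:
            continue  # handled by the merged edge below
        edges.append((n.parent, n, n.length or 0.0))
    if len(root.children) == 2:
        a, b = root.children
        edges.append((a, b, (a.length or 0.0) + (b.length or 0.0)))
    return edges


def midpoint_root(tree: Tree) -> Tree:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    If the midpoint falls exactly on an existing node, that node becomes the
    root. Raises if every branch length is zero (no unique midpoint).
    """
    tree = tree.copy()
    edges = _unrooted_edges(tree)
    if all(e[2] == 0 for e in edges):
        raise TreeError("all branch lengths zero: midpoint undefined")

    adj: dict[Node, list[tuple[Node, float]]] = {}
    for a, b, w in edges:
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    if len(tree.root.children) == 2:
        adj.pop(tree.root, None)

    def dists_from(src: Node) -> dict[Node, float]:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        return seen

    leaves = tree.leaves()
    best = (-1.0, None, None)
    for lf in leaves:
        d = dists_from(lf)
        for other in leaves:
            if other is lf:
                continue
            if d[other] > best[0]:
                best = (d[other], lf, other)
    diameter, end_a, end_b = best

    # walk the path from end_a to end_b, find the edge containing diameter/2
    parent_on_path: dict[Node, Node] = {}
    stack = [end_a]
    seen = {end_a}
    while stack:
        u = stack.pop()
        for v, _ in adj[u]:
            if v not in seen:
                seen.add(v)
                parent_on_path[v] = u
                stack.append(v)
    path = [end_b]
    while path[-1] is not end_a:
        path.append(parent_on_path[path[-1]])
    path.reverse()  # end_a ... end_b

    half = diameter / 2.0
    acc = 0.0
    wmap = {}
    for a, b, w in edges:
        wmap[(id(a), id(b))] = w
        wmap[(id(b), id(a))] = w
    for u, v in itertools.pairwise(path):
        w = wmap[(id(u), id(v))]
        if acc + w >= half - 1e-15:
            offset = half - acc  # distance from u along edge (u, v)
            return _reroot_on_edge(tree, u, v, w, offset)
        acc += w
    raise TreeError("midpoint search failed")  # pragma: no cover


def _neighbor_map(tree: Tree):
    nbrs: dict[Node, list[tuple[Node, float]]] = {n: [] for n in tree.postorder()}
    root = tree.root
    binary_root = len(root.children) == 2
    for n in tree.postorder():
        if n is root:
            continue
        if binary_root and n.parent is root:
            continue
        nbrs[n.parent].append((n, n.length or 0.0))
        nbrs[n].append((n.parent, n.length or 0.0))
    if binary_root:
        a, b = root.children
        w = (a.length or 0.0) + (b.length or 0.0)
        nbrs[a].append((b, w))
        nbrs[b].append((a, w))
    return nbrs


def _reroot_on_edge(tree: Tree, u: Node, v: Node, w: float, offset: float) -> Tree:
    """Build a new rooted tree with the root on edge (u, v) at ``offset`` from u."""
    eps = 1e-12 * max(w, 1.0)
    nbrs = _neighbor_map(tree)

    def build(node: Node, came_from: Optional[Node], length: Optional[float]) -> Node:
        m = Node(node.label if (node.is_leaf or node.label) else None, length)
        for nb, bw in nbrs[node]:
            if nb is came_from:
                continue
            m.add_child(build(nb, node, bw))
        return m

    if offset <= eps or w - offset <= eps:
        anchor = u if offset <= eps else v
        new_root = build(anchor, None, None)
    else:
        new_root = Node(None, None)
        new_root.add_child(build(u, v, offset))
        new_root.add_child(build(v, u, w - offset))
    out = Tree(new_root)
    out.validate(allow_root_trifurcation=True)
    return out


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric difference of non-trivial bipartitions)."""
    la, lb = set(a.leaf_labels()), set(b.leaf_labels())
    if la != lb:
        raise TreeError("trees are on different leaf sets")
    full = frozenset(la)

    def biparts(t: Tree) -> set[frozenset]:
        out = set()
        for node, clade in t.clades().items():
            side = min(clade, full - clade, key=lambda s: (len(s), sorted(s)))
            if 1 < len(side):
                out.add(frozenset(side))
        return out

    return len(biparts(a) ^ biparts(b))
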