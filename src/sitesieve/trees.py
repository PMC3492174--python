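"""Lightweight rooted-representation phylogenetic trees.

Trees are stored as rooted node structures but compared and manipulated as
unrooted objects (split sets, NNI rearrangements).  Newick parsing is
delegated to dendropy; the in-memory form is a minimal parent/children
structure that the likelihood engine can traverse cheaply.
"""

from __future__ import annotations


import dendropy
import numpy as np

__all__ = ["Node", "Tree", "all_unrooted_topologies", "random_topology", "rf_distance"]


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name=None, length=None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A phylogenetic tree with optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label, dnode.edge.length)
            for ch in dnode.child_nodes():
                node.add(convert(ch))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if node.length is not None:
                s += f":{node.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    # ------------------------------------------------------------ traversal
    def postorder(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def leaves(self) -> list[Node]:
        """All taxon tips, including a named root acting as a leaf (the
        leaf-rooted representation used for NNI)."""
        out = [n for n in self.postorder() if n.is_leaf]
        if self.root.children and self.root.name:
            out.append(self.root)
        return out

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Nodes carrying an edge to their parent (i.e. all non-root nodes)."""
        return [n for n in self.postorder() if n.parent is not None]

    def branch_lengths(self) -> list[float]:
        return [n.length for n in self.edges() if n.length is not None]

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length)
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root))

    # ------------------------------------------------------- unrooted view
    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial unrooted splits, each encoded as the side excluding
        the lexicographically smallest leaf."""
        names = set(self.leaf_names)
        ref = min(names)
        out = set()
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = {n.name}
            else:
                below[id(n)] = set().union(*(below[id(c)] for c in n.children))
            if n.parent is not None:
                side = below[id(n)]
                side = names - side if ref in side else side
                if 2 <= len(side) <= len(names) - 2:
                    out.add(frozenset(side))
        return frozenset(out)

    def same_topology(self, other: "Tree") -> bool:
        return (
            set(self.leaf_names) == set(other.leaf_names)
            and self.splits() == other.splits()
        )

    def has_split(self, side) -> bool:
        names = set(self.leaf_names)
        side = set(side)
        ref = min(names)
        if ref in side:
            side = names - side
        return frozenset(side) in self.splits()

    def reroot_at_leaf(self, name: str | None = None) -> "Tree":
        """Return a copy rooted at a leaf (root has that leaf's name and a
        single child); branch lengths are preserved on the same edges."""
        adj: dict[int, list[tuple[Node, float | None]]] = {}
        nodes: dict[int, Node] = {}
        for n in self.postorder():
            nodes[id(n)] = n
            adj.setdefault(id(n), [])
            if n.parent is not None:
                adj[id(n)].append((n.parent, n.length))
                adj.setdefault(id(n.parent), []).append((n, n.length))
        # drop a redundant degree-2 old root (rooted binary newick)
        old_root = self.root
        if len(old_root.children) == 2 and old_root.parent is None:
            (a, la), (b, lb) = adj[id(old_root)]
            tot = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
            adj[id(a)] = [(x, l) for x, l in adj[id(a)] if x is not old_root] + [(b, tot)]
            adj[id(b)] = [(x, l) for x, l in adj[id(b)] if x is not old_root] + [(a, tot)]
            del adj[id(old_root)]
        tips = {
            n.name: n
            for n in nodes.values()
            if id(n) in adj and (n.is_leaf or (n is self.root and n.name))
        }
        if name is None:
            name = min(tips)
        start = tips[name]

        def build(src: Node, came_from: Node | None, length) -> Node:
            out = Node(src.name, length)
            for nbr, l in adj[id(src)]:
                if nbr is not came_from:
                    out.add(build(nbr, src, l))
            return out

        return Tree(build(start, None, None))

    # ---------------------------------------------------------------- NNI
    def nni_neighbors(self) -> list["Tree"]:
        """All trees one nearest-neighbor interchange away (unrooted sense)."""
        base = self.reroot_at_leaf()
        out = []
        nodes = base.postorder()
        for vi, v in enumerate(nodes):
            u = v.parent
            # internal edge of the unrooted tree: v internal, u internal
            # (u is internal unless it is the leaf acting as root)
            if v.is_leaf or u is None or u is base.root:
                continue
            w = next(c for c in u.children if c is not v)
            for ci in range(len(v.children)):
                t = base.copy()
                tn = t.postorder()
                v2, u2 = tn[vi], tn[vi].parent
                w2 = next(c for c in u2.children if c is not v2)
                c2 = v2.children[ci]
                u2.children[u2.children.index(w2)] = c2
                v2.children[ci] = w2
                c2.parent, w2.parent = u2, v2
                out.append(t)
        return out


def rf_distance(a: Tree, b: Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric split difference)."""
    return len(a.splits() ^ b.splits())


def _tuple_to_tree(tup, default_length: float | None) -> Tree:
    def build(t) -> Node:
        if isinstance(t, str):
            return Node(t, default_length)
        n = Node(None, default_length)
        for c in t:
            n.add(build(c))
        return n

    root = Node(None, None)
    for c in tup:
        root.add(build(c))
    return Tree(root)


def all_unrooted_topologies(names: list[str], default_length: float | None = 0.1):
    """Enumerate all unrooted binary topologies by stepwise leaf addition.

    Counts follow (2n-5)!!; enumeration is only practical for n <= 8.
    """
    names = list(names)
    if len(names) > 8:
        raise ValueError(
            f"exhaustive enumeration limited to 8 taxa, got {len(names)}; use NNI search"
        )
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")

    def insert_into(tree, leaf):
        # tree is a tuple of 3 subtrees (unrooted, multifurcating root of deg 3)
        def edges(sub, path):
            yield path
            if not isinstance(sub, str):
                for i, c in enumerate(sub):
                    yield from edges(c, path + (i,))

        def attach(sub, path, leaf):
            if not path:
                return (sub, leaf)
            i = path[0]
            return tuple(
                attach(c, path[1:], leaf) if j == i else c for j, c in enumerate(sub)
            )

        for top_i in range(3):
            for path in edges(tree[top_i], (top_i,)):
                i0 = path[0]
                yield tuple(
                    attach(tree[j], path[1:], leaf) if j == i0 else tree[j]
                    for j in range(3)
                )

    trees = [tuple(names[:3])]
    for leaf in names[3:]:
        trees = [t2 for t in trees for t2 in insert_into(t, leaf)]
    return [_tuple_to_tree(t, default_length) for t in trees]


def random_topology(names: list[str], rng: np.random.Generator,
                    mean_length: float = 0.1) -> Tree:
    """Random binary topology via sequential random edge attachment, with
    exponential branch lengths."""
    names = list(names)
    order = list(rng.permutation(len(names)))
    base = tuple(names[i] for i in order[:3])
    tree = base
    for idx in order[3:]:
        options = list(_enumerate_insertions(tree, names[idx]))
        tree = options[int(rng.integers(len(options)))]
    t = _tuple_to_tree(tree, None)
    for n in t.edges():
        n.length = float(rng.exponential(mean_length))
    return t


def _enumerate_insertions(tree, leaf):
    def edges(sub, path):
        yield path
        if not isinstance(sub, str):
            for i, c in enumerate(sub):
                yield from edges(c, path + (i,))

    def attach(sub, path, leaf):
        if not path:
            return (sub, leaf)
        i = path[0]
        return tuple(
            attach(c, path[1:], leaf) if j == i else c for j, c in enumerate(sub)
        )

    for top_i in range(3):
        for path in edges(tree[top_i], (top_i,)):
            i0 = path[0]
            yield tuple(
                attach(tree[j], path[1:], leaf) if j == i0 else tree[j]
                for j in range(3)
            )
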