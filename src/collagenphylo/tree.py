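"""A light phylogenetic tree structure for likelihood computation.

dendropy handles Newick/NEXUS parsing and writing; this class keeps the
in-memory representation small and fast for the pruning recursion, branch
re-optimization, rerooting and NNI moves.  An *unrooted* tree is represented
rooted at an internal node with three (or more) children; likelihoods under
a reversible model do not depend on that choice.
"""

from __future__ import annotations

from typing import Callable, Iterator

import dendropy


class Node:
    __slots__ = ("name", "children", "parent", "length")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.length = length  # edge length to parent

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_edges(self) -> list[Node]:
        """Child endpoints of internal (non-pendant) edges."""
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and n.parent is not None
        ]

    def branches(self) -> list[Node]:
        """All nodes carrying an edge (everything but the root)."""
        return [n for n in self.postorder() if n.parent is not None]

    # -- copying ------------------------------------------------------------

    def copy(self) -> "Tree":
        return self.copy_with_map()[0]

    def copy_with_map(self) -> tuple["Tree", dict[int, Node]]:
        mapping: dict[int, Node] = {}

        def _clone(node: Node) -> Node:
            c = Node(node.name, node.length)
            mapping[id(node)] = c
            for child in node.children:
                c.add(_clone(child))
            return c

        return Tree(_clone(self.root)), mapping

    # -- rooting ------------------------------------------------------------

    def reroot_at(self, node: Node) -> None:
        """Make an internal node the root, reversing parent chains.

        Edge lengths stay attached to the same edges.  A former degree-2
        root is suppressed (its two incident edges merged).
        """
        if node.is_leaf:
            raise ValueError("cannot root at a leaf")
        if node is self.root:
            return
        # Path from node up to old root.
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        orig_lengths = [n.length for n in path]
        # Reverse each parent edge along the path; the reversed edge keeps
        # the original child-edge length.
        for i, (child, parent) in enumerate(zip(path, path[1:])):
            parent.children.remove(child)
            parent.length = orig_lengths[i]
            child.add(parent)
        node.parent = None
        node.length = 0.0
        old_root = path[-1]
        if len(old_root.children) == 1:
            # Suppress degree-2 node: splice its single child into its parent.
            only = old_root.children[0]
            parent = old_root.parent
            only.length += old_root.length
            parent.children[parent.children.index(old_root)] = only
            only.parent = parent
        self.root = node

    def unroot(self) -> None:
        """Ensure the root is a trifurcation (unrooted representation)."""
        while len(self.root.children) == 2:
            a, b = self.root.children
            keep, merge = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                return  # two-leaf tree, nothing to do
            merge.length += keep.length
            new_root = keep
            new_root.parent = None
            new_root.length = 0.0
            new_root.add(merge)
            self.root = new_root

    def root_between(self, taxon: str, fraction: float = 0.5) -> "Tree":
        """Return a copy rooted on the pendant edge of ``taxon`` (outgroup
        display rooting)."""
        t2, mapping = self.copy_with_map()
        leaf = next(n for n in t2.postorder() if n.name == taxon)
        parent = leaf.parent
        t2.reroot_at(parent if parent is not None else t2.root)
        edge = leaf.length
        parent = leaf.parent
        parent.children.remove(leaf)
        new_root = Node(None, 0.0)
        leaf.length = edge * fraction
        new_root.add(leaf)
        old = t2.root
        old.length = edge * (1 - fraction)
        # keep remaining structure under the old root
        new_root.add(old)
        t2.root = new_root
        return t2

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, canonicalized as the side not containing
        the alphabetically first taxon."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.parent is None or node.is_leaf:
                continue
            side = frozenset(n.name for n in Tree(node).leaves())
            if ref in side:
                side = all_taxa - side
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(side)
        return out

    def topology_id(self) -> frozenset[frozenset[str]]:
        """Hashable unrooted-topology identifier."""
        return frozenset(self.bipartitions())

    def find_clade_mrca(self, taxa: set[str]) -> Node:
        """Most recent common ancestor of a taxon set (rooted tree)."""
        want = set(taxa)
        below: dict[int, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = {node.name}
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= below[id(c)]
                below[id(node)] = s
            if want <= below[id(node)]:
                return node
        raise ValueError(f"taxa {sorted(want)} not all present in tree")

    # -- Newick I/O ---------------------------------------------------------

    def to_newick(
        self,
        lengths: bool = True,
        label: Callable[[Node], str | None] | None = None,
        precision: int = 8,
    ) -> str:
        def _fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(_fmt(c) for c in node.children) + ")"
                if label is not None:
                    lab = label(node)
                    if lab:
                        s += lab
            if lengths and node.parent is not None:
                s += f":{node.length:.{precision}g}"
            return s

        return _fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "Tree":
        def _convert(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else None
            n = Node(name, dn.edge.length if dn.edge.length is not None else 0.0)
            for c in dn.child_nodes():
                n.add(_convert(c))
            return n

        return cls(_convert(dt.seed_node))

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            preserve_underscores=True,
            taxon_namespace=taxon_namespace,
        )


def nni_neighbors(tree: Tree) -> list[Tree]:
    """All nearest-neighbour-interchange neighbours of an unrooted tree.

    The tree must be in unrooted representation (trifurcating root).  Each
    internal edge yields two alternative topologies.
    """
    neighbors: list[Tree] = []
    edges = [
        (id(v.parent), id(v)) for v in tree.internal_edges()
    ]
    for u_id, v_id in edges:
        for swap_idx in (0, 1):
            t2, mapping = tree.copy_with_map()
            u2 = mapping[u_id]
            v2 = mapping[v_id]
            t2.reroot_at(u2)
            # After rerooting at u, v is a child of u with its own children.
            assert v2.parent is u2
            b = next(c for c in u2.children if c is not v2)
            c = v2.children[swap_idx]
            # Swap subtrees b and c across the internal edge u-v.
            u2.children[u2.children.index(b)] = c
            v2.children[v2.children.index(c)] = b
            b.parent, c.parent = v2, u2
            neighbors.append(t2)
    return neighbors


def random_topology(taxa: list[str], rng) -> Tree:
    """Uniform-ish random unrooted binary topology via sequential addition."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    taxa = list(taxa)
    rng.shuffle(taxa)
    root = Node()
    for t in taxa[:3]:
        root.add(Node(t, 0.1))
    tree = Tree(root)
    for t in taxa[3:]:
        edges = tree.branches()
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node(None, target.length / 2)
        target.length /= 2
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(t, 0.1))
    return tree
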