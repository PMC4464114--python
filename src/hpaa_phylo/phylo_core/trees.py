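"""Minimal phylogenetic tree structure with Newick I/O.

Trees are rooted node structures; an unrooted tree is represented by a root
of degree three (the usual unrooted-Newick convention).  Newick parsing is
delegated to dendropy; this class only adds the small amount of structure
the likelihood engine and the reconciliation code need: postorder traversal,
leaf sets, bipartitions, and rerooting on an edge.
"""

from __future__ import annotations

from typing import Iterator

import dendropy

__all__ = ["Node", "Tree"]


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.label for n in self.postorder() if n.is_leaf)

    def copy(self) -> "Node":
        new = Node(self.label, self.length)
        for child in self.children:
            new.add(child.copy())
        return new

    def _newick(self, with_lengths: bool) -> str:
        if self.is_leaf:
            s = self.label or ""
        else:
            s = "(" + ",".join(c._newick(with_lengths) for c in self.children) + ")"
            if self.label:
                s += self.label
        if with_lengths and self.length is not None:
            s += f":{self.length:.8g}"
        return s


class Tree:
    """A rooted tree; degree-3 root encodes an unrooted binary tree."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -------------------------------------------------------

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
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        root = convert(dt.seed_node)
        root.length = None
        return cls(root)

    @classmethod
    def from_nested(cls, nested) -> "Tree":
        """Build from nested tuples of leaf labels, e.g. ``(("a","b"),"c")``."""

        def convert(item) -> Node:
            if isinstance(item, str):
                return Node(label=item)
            node = Node()
            for sub in item:
                node.add(convert(sub))
            return node

        return cls(convert(nested))

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    # -- queries ------------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def edges(self) -> list[Node]:
        """Every non-root node; each identifies the edge above it."""
        return [n for n in self.postorder() if n is not self.root]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.postorder() if not n.is_leaf and n is not self.root)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted tree, as the leaf set on one side.

        Each split is canonicalized to the side *not* containing the
        alphabetically first leaf, so bipartition sets from differently
        rooted copies of the same unrooted tree compare equal.
        """
        all_leaves = self.leaf_names()
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.edges():
            below = node.leaf_names()
            side = all_leaves - below if ref in below else below
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def find_clade(self, labels: frozenset[str]) -> Node | None:
        """Node whose subtree leaf set equals ``labels``, if any."""
        for node in self.postorder():
            if node.leaf_names() == labels:
                return node
        return None

    def has_bipartition(self, labels) -> bool:
        """True if ``labels`` | rest is an edge-induced split of the unrooted tree."""
        labels = frozenset(labels)
        all_leaves = self.leaf_names()
        if not labels < all_leaves:
            raise ValueError("clade must be a proper subset of the leaf set")
        if not (2 <= len(labels) <= len(all_leaves) - 2):
            raise ValueError("clade must leave at least two leaves on each side")
        ref = min(all_leaves)
        side = all_leaves - labels if ref in labels else labels
        return side in self.bipartitions()

    # -- rerooting ----------------------------------------------------------

    def rerooted_on_edge(self, labels_below: frozenset[str]) -> "Tree | None":
        """Root the unrooted tree on the edge above the clade ``labels_below``.

        Returns a new tree whose root has exactly two children: the subtree
        with leaf set ``labels_below`` and the remainder.  The edge length is
        split equally between the two root children (irrelevant for
        reconciliation; likelihoods are invariant under reversibility).
        Returns ``None`` when no edge induces that split.
        """
        labels_below = frozenset(labels_below)
        target = None
        for node in self.postorder():
            if node is not self.root and node.leaf_names() == labels_below:
                target = node
                break
        if target is None:
            return None

        # undirected adjacency over the original nodes
        adj: dict[Node, list[tuple[Node, float | None]]] = {}
        for node in self.postorder():
            for child in node.children:
                adj.setdefault(node, []).append((child, child.length))
                adj.setdefault(child, []).append((node, child.length))

        def _add(a: float | None, b: float | None) -> float | None:
            if a is None and b is None:
                return None
            return (a or 0.0) + (b or 0.0)

        def build(node: Node, came_from: Node, length: float | None) -> Node:
            nbrs = [(n, l) for (n, l) in adj.get(node, []) if n is not came_from]
            if node.children and len(nbrs) == 1:
                # degree-2 point (the old root seen from below): suppress it
                nxt, l = nbrs[0]
                return build(nxt, node, _add(length, l))
            new = Node(node.label, length)
            for nxt, l in nbrs:
                new.add(build(nxt, node, l))
            return new

        half = target.length / 2.0 if target.length is not None else None
        new_root = Node()
        new_root.add(build(target, target.parent, half))
        new_root.add(build(target.parent, target, half))
        return Tree(new_root)

    # -- output -------------------------------------------------------------

    def to_newick(self, with_lengths: bool = True) -> str:
        has_any = any(n.length is not None for n in self.edges())
        return self.root._newick(with_lengths and has_any) + ";"

    def __repr__(self) -> str:
        return f"Tree({self.to_newick()})"
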