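"""Exhaustive enumeration of unrooted binary tree topologies.

Enumeration is by stepwise leaf addition: every unrooted binary topology on
n labels arises exactly once by inserting the n-th label into each edge of
each (n-1)-label topology, giving the double-factorial count (2n-5)!!.
Constraint groups collapse a set of sequence ids into one operational
taxonomic unit (OTU) whose fixed internal subtree is re-expanded verbatim
in the emitted trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import Node, Tree

__all__ = ["ConstraintGroups", "enumerate_topologies", "n_unrooted_topologies"]

MAX_FREE_OTUS = 9


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labelled leaves."""
    if n < 3:
        return 1
    count = 1
    for k in range(3, 2 * n - 4, 2):
        count *= k
    return count


@dataclass
class ConstraintGroups:
    """Mapping OTU label -> fixed Newick subtree over its member ids.

    Example: ``{"g1": "((mouse_Emx1,chick_Emx1),fish_Emx1)"}`` collapses the
    gnathostome Emx1 sequences into one OTU with a frozen internal topology.
    """

    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members: set[str] = set()
        self._subtrees: dict[str, Node] = {}
        for label, newick in self.groups.items():
            sub = Tree.from_newick(newick if newick.endswith(";") else newick + ";")
            leaves = sub.leaf_names()
            if members & leaves:
                raise ValueError("constraint group member sets must be disjoint")
            members |= leaves
            self._subtrees[label] = sub.root

    def expand(self, label: str) -> Node | None:
        node = self._subtrees.get(label)
        return node.copy() if node is not None else None


def _insertions(tree, leaf):
    """All trees obtained by inserting ``leaf`` on each edge of ``tree``.

    Trees are nested tuples with a ternary root (the unrooted convention);
    an edge is identified with the subtree below it.
    """
    results = []

    def recurse(subtree):
        """All ways to insert the new leaf into ``subtree`` or its edges."""
        variants = [(subtree, leaf)]
        if isinstance(subtree, tuple):
            for i, child in enumerate(subtree):
                for replacement in recurse(child):
                    variants.append(subtree[:i] + (replacement,) + subtree[i + 1 :])
        return variants

    for i, child in enumerate(tree):
        for replacement in recurse(child):
            results.append(tree[:i] + (replacement,) + tree[i + 1 :])
    return results


def enumerate_topologies(
    otus: list[str],
    constraints: ConstraintGroups | None = None,
    force: bool = False,
) -> list[Tree]:
    """All distinct unrooted binary topologies over the given OTU labels.

    Constraint-group labels are expanded back into their fixed subtrees in
    the returned trees.  Enumeration over more than 9 collapsed OTUs is
    refused unless ``force`` is set (the count grows double-factorially).
    """
    labels = sorted(otus)
    if len(labels) != len(set(labels)):
        raise ValueError("OTU labels must be unique")
    if len(labels) < 3:
        raise ValueError("need at least 3 OTUs after collapsing constraint groups")
    if len(labels) > MAX_FREE_OTUS and not force:
        raise ValueError(
            f"{len(labels)} OTUs would give {n_unrooted_topologies(len(labels))} topologies; "
            "pass force=True to enumerate anyway"
        )
    partial = [tuple(labels[:3])]
    for leaf in labels[3:]:
        partial = [t for tree in partial for t in _insertions(tree, leaf)]

    def to_tree(nested) -> Tree:
        def convert(item) -> Node:
            if isinstance(item, str):
                expanded = constraints.expand(item) if constraints else None
                return expanded if expanded is not None else Node(label=item)
            node = Node()
            for sub in item:
                node.add(convert(sub))
            return node

        return Tree(convert(nested))

    return [to_tree(t) for t in partial]
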