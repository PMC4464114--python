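"""Gene-duplication counting by gene-tree/species-tree reconciliation.

The species tree is fixed to ``(outgroup, (cyclostome, gnathostome))`` and
each gene-tree leaf is assigned to one of the three groups.  LCA
reconciliation maps every internal gene-tree node to the most recent
species-tree node containing its descendant species; a node is a
duplication exactly when it maps to the same species-tree node as at least
one of its children.  Duplications at the cyclostome-gnathostome ancestor
count as before the split (N_bef); duplications inside the gnathostome or
cyclostome lineages count as N_aft and N_cyc.  BP-weighted sums over an
exhaustive topology set give the probabilistic counts.

In the default mode every topology is rooted on the outgroup edge, which
always exists when the outgroup is a single collapsed OTU, and N_unk = 0.
The optional rooting-agnostic mode re-reconciles under every possible
branch rooting and books timing-unstable duplications as N_unk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_core import Tree

__all__ = [
    "SpeciesAssignment",
    "DupCounts",
    "root_on_outgroup",
    "reconcile_count",
    "probabilistic_counts",
    "per_topology_table",
]

CYCLOSTOME = "cyclostome"
GNATHOSTOME = "gnathostome"
OUTGROUP = "outgroup"
_GROUPS = (CYCLOSTOME, GNATHOSTOME, OUTGROUP)


@dataclass(frozen=True)
class SpeciesAssignment:
    """Leaf label -> {cyclostome, gnathostome, outgroup}."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in _GROUPS}
        if bad:
            raise ValueError(f"unknown species groups {sorted(bad)}")
        if OUTGROUP not in self.mapping.values():
            raise ValueError("at least one leaf must be assigned to the outgroup")

    def group(self, label: str) -> str:
        try:
            return self.mapping[label]
        except KeyError:
            raise ValueError(f"leaf {label!r} has no species assignment") from None

    def outgroup_labels(self) -> frozenset[str]:
        return frozenset(l for l, g in self.mapping.items() if g == OUTGROUP)

    @classmethod
    def read_tsv(cls, path) -> "SpeciesAssignment":
        mapping = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, group = line.split("\t")[:2]
                mapping[label] = group
        return cls(mapping)


@dataclass(frozen=True)
class DupCounts:
    """Duplication counts by timing class (integers per topology,
    reals after BP weighting)."""

    n_bef: float = 0.0
    n_aft: float = 0.0
    n_cyc: float = 0.0
    n_unk: float = 0.0

    @property
    def total(self) -> float:
        return self.n_bef + self.n_aft + self.n_cyc + self.n_unk

    def __add__(self, other: "DupCounts") -> "DupCounts":
        return DupCounts(
            self.n_bef + other.n_bef,
            self.n_aft + other.n_aft,
            self.n_cyc + other.n_cyc,
            self.n_unk + other.n_unk,
        )

    def scaled(self, w: float) -> "DupCounts":
        return DupCounts(w * self.n_bef, w * self.n_aft, w * self.n_cyc, w * self.n_unk)


def root_on_outgroup(tree: Tree, assignment: SpeciesAssignment) -> Tree | None:
    """Rooted ingroup tree obtained by rooting on the outgroup stem edge.

    Returns the ingroup subtree (outgroup leaves removed) rooted at the
    split, or ``None`` when no single edge separates all outgroup leaves
    from the ingroup.
    """
    leaves = tree.leaf_names()
    out_labels = assignment.outgroup_labels() & leaves
    if not out_labels:
        raise ValueError("tree contains no outgroup leaf")
    if len(leaves - out_labels) < 1:
        raise ValueError("tree contains no ingroup leaves")
    if len(out_labels) == len(leaves) - 1:
        # single ingroup leaf: trivially rooted
        rerooted = tree.rerooted_on_edge(leaves - out_labels)
    else:
        rerooted = tree.rerooted_on_edge(out_labels)
    if rerooted is None:
        return None
    for child in rerooted.root.children:
        if child.leaf_names() == leaves - out_labels:
            child.parent = None
            return Tree(child)
    return None


def _join(a: str, b: str) -> str:
    """LCA in the species tree (outgroup, (cyclostome, gnathostome)).

    Nodes: the three leaves, V = the cyclostome-gnathostome ancestor and
    R = the root above the outgroup divergence.
    """
    if a == b:
        return a
    if "R" in (a, b) or OUTGROUP in (a, b):
        return "R"
    # remaining labels are among {cyclostome, gnathostome, V}
    return "V"


def reconcile_count(rooted_tree: Tree, assignment: SpeciesAssignment) -> DupCounts:
    """LCA reconciliation duplication counts for a rooted binary gene tree.

    The tree may be an ingroup-only tree (leaves mapped to cyclostome or
    gnathostome) or contain outgroup leaves; duplications ancestral to the
    outgroup divergence are counted as N_unk.
    """
    counts = {"V": 0, GNATHOSTOME: 0, CYCLOSTOME: 0, "R": 0, OUTGROUP: 0}

    def walk(node) -> str:
        if node.is_leaf:
            return assignment.group(node.label)
        if len(node.children) != 2:
            raise ValueError("reconciliation requires a fully binary rooted tree")
        left = walk(node.children[0])
        right = walk(node.children[1])
        here = _join(left, right)
        if here in (left, right):
            counts[here] += 1
        return here

    walk(rooted_tree.root)
    return DupCounts(
        n_bef=counts["V"],
        n_aft=counts[GNATHOSTOME],
        n_cyc=counts[CYCLOSTOME],
        n_unk=counts["R"] + counts[OUTGROUP],
    )


def _agnostic_counts(tree: Tree, assignment: SpeciesAssignment) -> DupCounts:
    """Best-effort rooting-agnostic counts.

    Every branch rooting is reconciled (with the outgroup leaves kept in
    the tree); among the rootings with the minimal total duplication count,
    each timing class receives the count on which all such rootings agree
    (their minimum), and the remainder of the minimal total is booked as
    N_unk, the timing-unresolved share.
    """
    leaves = tree.leaf_names()
    candidates = []
    for node in tree.edges():
        below = node.leaf_names()
        if below == leaves:
            continue
        rooted = tree.rerooted_on_edge(below)
        if rooted is None:
            continue
        candidates.append(reconcile_count(rooted, assignment))
    if not candidates:
        raise ValueError("no admissible rooting found")
    min_total = min(c.total for c in candidates)
    minimal = [c for c in candidates if c.total == min_total]
    bef = min(c.n_bef for c in minimal)
    aft = min(c.n_aft for c in minimal)
    cyc = min(c.n_cyc for c in minimal)
    return DupCounts(bef, aft, cyc, min_total - bef - aft - cyc)


def topology_counts(tree: Tree, assignment: SpeciesAssignment, mode: str = "outgroup") -> DupCounts:
    """Integer duplication counts of one (unrooted) topology."""
    if mode == "outgroup":
        rooted = root_on_outgroup(tree, assignment)
        if rooted is None:
            raise ValueError(
                "topology cannot be rooted on the outgroup edge; use mode='agnostic'"
            )
        return reconcile_count(rooted, assignment)
    if mode == "agnostic":
        return _agnostic_counts(tree, assignment)
    raise ValueError(f"unknown mode {mode!r}")


def probabilistic_counts(
    topologies: list[Tree],
    bp,
    assignment: SpeciesAssignment,
    mode: str = "outgroup",
) -> DupCounts:
    """BP-weighted duplication counts N_bef, N_aft, N_cyc, N_unk."""
    bp = np.asarray(bp, dtype=float)
    if len(bp) != len(topologies):
        raise ValueError("BP vector and topology list differ in length")
    if abs(bp.sum() - 1.0) > 1e-6:
        raise ValueError("BP vector must be normalized")
    total = DupCounts()
    for weight, tree in zip(bp, topologies):
        total = total + topology_counts(tree, assignment, mode).scaled(float(weight))
    return total


def per_topology_table(
    topologies: list[Tree],
    bp,
    assignment: SpeciesAssignment,
    mode: str = "outgroup",
) -> pd.DataFrame:
    """Per-topology integer counts plus the BP-weighted summary row."""
    bp = np.asarray(bp, dtype=float)
    rows = []
    for weight, tree in zip(bp, topologies):
        c = topology_counts(tree, assignment, mode)
        rows.append(
            {
                "topology": tree.to_newick(with_lengths=False),
                "bp": float(weight),
                "n_bef": c.n_bef,
                "n_aft": c.n_aft,
                "n_cyc": c.n_cyc,
                "n_unk": c.n_unk,
            }
        )
    table = pd.DataFrame(rows)
    weighted = probabilistic_counts(topologies, bp, assignment, mode)
    table.loc[len(table)] = {
        "topology": "BP-weighted",
        "bp": float(bp.sum()),
        "n_bef": weighted.n_bef,
        "n_aft": weighted.n_aft,
        "n_cyc": weighted.n_cyc,
        "n_unk": weighted.n_unk,
    }
    return table
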