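"""Protein distances, neighbor joining and bootstrap clade support."""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .alignment import Alignment
from .trees import Node, Tree

__all__ = ["protein_distance", "distance_matrix", "nj_tree", "bootstrap_support"]


def protein_distance(seq1: str, seq2: str) -> float:
    """Kimura-corrected protein distance over ungapped shared columns.

    d = -ln(1 - p - p^2/5) where p is the observed fraction of differing
    residues.  Returns ``inf`` (a saturation marker) when p exceeds the
    correction's domain (p >= ~0.8541).
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    pairs = [
        (a, b)
        for a, b in zip(seq1.upper(), seq2.upper())
        if a != "-" and b != "-"
    ]
    if not pairs:
        raise ValueError("no shared ungapped columns")
    p = sum(1 for a, b in pairs if a != b) / len(pairs)
    arg = 1.0 - p - p * p / 5.0
    if arg <= 0.0:
        return math.inf
    return -math.log(arg)


def distance_matrix(alignment: Alignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise Kimura protein distance matrix of an alignment."""
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(alignment.rows[i], alignment.rows[j])
    return d, list(alignment.ids)


def nj_tree(dist, labels: list[str]) -> Tree:
    """Canonical neighbor-joining tree from a symmetric distance matrix.

    Ties in the minimum-Q criterion are broken toward the pair whose
    (sorted) cluster names compare smallest, making the agglomeration
    deterministic.  The final three clusters are joined at an unresolved
    (ternary) root with branch lengths from the three-point formulas.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distances must be non-negative with a zero diagonal")
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        root = Node()
        root.add(Node(labels[0], d[0, 1] / 2.0))
        root.add(Node(labels[1], d[0, 1] / 2.0))
        return Tree(root)

    nodes: list[Node] = [Node(lbl) for lbl in labels]
    names: list[str] = list(labels)  # smallest member label names each cluster
    d = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                key = (q, tuple(sorted((names[i], names[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi = max(vi, 0.0)
        vj = max(vj, 0.0)
        parent = Node()
        parent.add(nodes[i]).length = vi
        parent.add(nodes[j]).length = vj
        new_row = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[-1, : m - 2] = d2[: m - 2, -1] = new_row[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # resolve the last three clusters around a ternary root
    root = Node()
    v0 = max(0.0, (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0)
    v1 = max(0.0, (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0)
    v2 = max(0.0, (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0)
    for node, v in zip(nodes, (v0, v1, v2)):
        root.add(node).length = v
    return Tree(root)


def nj_from_alignment(alignment: Alignment) -> Tree:
    """Neighbor-joining tree from Kimura protein distances of an alignment."""
    d, labels = distance_matrix(alignment)
    return nj_tree(d, labels)


def bootstrap_support(
    alignment: Alignment,
    method: Callable[[Alignment], Tree] | None = None,
    n_replicates: int = 100,
    seed: int | None = None,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Nonparametric bootstrap support for the point-estimate tree's splits.

    Columns are resampled with replacement; support of each bipartition of
    the point tree is the fraction of replicate trees containing it,
    reported on the 0-100 scale of the figures it backs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if len(alignment) < 4:
        raise ValueError("bootstrap support needs at least 4 sequences")
    method = method or nj_from_alignment
    rng = np.random.default_rng(seed)
    point_tree = method(alignment)
    splits = point_tree.bipartitions()
    hits = dict.fromkeys(splits, 0)
    for _ in range(n_replicates):
        rep_tree = method(alignment.resample_columns(rng))
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                hits[s] += 1
    support = {s: 100.0 * hits[s] / n_replicates for s in splits}
    return point_tree, support
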