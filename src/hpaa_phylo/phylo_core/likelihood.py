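"""Felsenstein pruning likelihoods and branch-length optimization.

Per-site log-likelihoods are computed by the pruning algorithm under the
reversible amino-acid model, vectorized over sites and gamma-rate
categories, with per-site rescaling against underflow and alignment-column
pattern compression.  Gaps and ambiguity characters are missing data
(partial likelihood 1 over all states).  The optional invariant-sites class
contributes ``p_inv * pi_c`` at sites whose observed residues are all equal
to ``c``.

Branch lengths are fitted by coordinate-wise bounded scalar optimization
(Brent) iterated over sweeps until the total log-likelihood improves by
less than a tolerance.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .model import SubstitutionModel
from .trees import Tree

__all__ = [
    "TreeLikelihood",
    "site_log_likelihoods",
    "optimize_branch_lengths",
    "estimate_alpha",
]

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0
_TINY = 1e-300


class TreeLikelihood:
    """Pruning engine bound to one alignment, tree shape and model.

    The tree's shape is frozen at construction; branch lengths are a
    mutable vector (one entry per non-root node, postorder), so the same
    engine serves both plain evaluation and branch-length optimization.
    """

    def __init__(self, alignment: Alignment, tree: Tree, model: SubstitutionModel):
        leaf_labels = {n.label for n in tree.leaves()}
        if set(alignment.ids) != leaf_labels:
            raise ValueError(
                f"alignment ids {sorted(alignment.ids)} do not match tree leaves {sorted(leaf_labels)}"
            )
        if alignment.n_columns == 0:
            raise ValueError("alignment has no columns")
        self.model = model
        self.tree = tree

        # postorder node indexing; root is last
        self._nodes = list(tree.postorder())
        self._index = {id(n): i for i, n in enumerate(self._nodes)}
        self._children = [[self._index[id(c)] for c in n.children] for n in self._nodes]
        self._leaf_row = {}

        codes = alignment.codes([n.label for n in self._nodes if n.is_leaf])
        leaf_order = [i for i, n in enumerate(self._nodes) if n.is_leaf]
        # column pattern compression
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self._pattern_codes = patterns.T  # (n_leaves, n_patterns)
        self._pattern_inverse = inverse
        self._pattern_counts = counts.astype(float)
        self.n_sites = alignment.n_columns
        n_pat = patterns.shape[0]

        # fixed leaf partials: (20, n_patterns) per leaf
        self._leaf_partials = {}
        for row, node_idx in enumerate(leaf_order):
            states = self._pattern_codes[row]
            part = np.zeros((20, n_pat))
            observed = states >= 0
            part[states[observed], np.nonzero(observed)[0]] = 1.0
            part[:, ~observed] = 1.0
            self._leaf_partials[node_idx] = part

        # invariant-class compatibility: pi_c if all observed states equal c
        pi = model.frequencies
        self._invariant_lik = np.zeros(n_pat)
        for p in range(n_pat):
            obs = self._pattern_codes[:, p]
            obs = obs[obs >= 0]
            if obs.size == 0:
                self._invariant_lik[p] = 1.0
            elif np.all(obs == obs[0]):
                self._invariant_lik[p] = pi[obs[0]]

        self.branch_lengths = np.array(
            [n.length if n.length is not None else 0.1 for n in self._nodes[:-1]], dtype=float
        )
        np.clip(self.branch_lengths, MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH, out=self.branch_lengths)

    # -- evaluation ---------------------------------------------------------

    def _pattern_log_likelihoods(self, lengths: np.ndarray) -> np.ndarray:
        model = self.model
        rates = model.variable_rates()
        weights = model.variable_weights()
        pmats = model.transition_matrices(lengths, rates)  # (E, C, 20, 20)
        n_pat = self._pattern_codes.shape[1]
        ncat = rates.size
        scaler = np.zeros(n_pat)
        partials: list[np.ndarray | None] = [None] * len(self._nodes)
        for i, children in enumerate(self._children):
            if not children:
                partials[i] = np.broadcast_to(self._leaf_partials[i], (ncat, 20, n_pat))
                continue
            prod = None
            for c in children:
                lifted = pmats[c] @ partials[c]
                prod = lifted if prod is None else prod * lifted
                partials[c] = None  # free memory early
            m = prod.max(axis=(0, 1))
            np.maximum(m, _TINY, out=m)
            prod /= m
            scaler += np.log(m)
            partials[i] = prod
        root = partials[-1]
        site_lik = weights @ (model.frequencies[None, None, :] @ root)[:, 0, :]
        if model.p_inv:
            # invariant class bypasses the scaler, so undo it for that term
            site_lik = site_lik + model.p_inv * self._invariant_lik * np.exp(-scaler)
        return np.log(np.maximum(site_lik, _TINY)) + scaler

    def log_likelihood(self, lengths: np.ndarray | None = None) -> float:
        lengths = self.branch_lengths if lengths is None else lengths
        return float(self._pattern_log_likelihoods(lengths) @ self._pattern_counts)

    def site_log_likelihoods(self, lengths: np.ndarray | None = None) -> np.ndarray:
        lengths = self.branch_lengths if lengths is None else lengths
        return self._pattern_log_likelihoods(lengths)[self._pattern_inverse]

    # -- optimization -------------------------------------------------------

    def optimize(
        self,
        tol: float = 1e-6,
        max_sweeps: int = 20,
        xatol: float = 1e-6,
    ) -> float:
        """Coordinate-ascent branch-length optimization; returns final logL.

        The log-likelihood never decreases across sweeps; a warning is
        issued if the sweep limit is reached before convergence.
        """
        lengths = self.branch_lengths
        best = self.log_likelihood(lengths)
        converged = False
        for _ in range(max_sweeps):
            start = best
            for e in range(lengths.size):
                current = lengths[e]

                def neg(t: float, e=e) -> float:
                    lengths[e] = t
                    return -self.log_likelihood(lengths)

                res = minimize_scalar(
                    neg,
                    bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                    method="bounded",
                    options={"xatol": xatol},
                )
                if -res.fun > best:
                    best = -res.fun
                    lengths[e] = res.x
                else:
                    lengths[e] = current
            if best - start < tol:
                converged = True
                break
        if not converged:
            warnings.warn("branch-length optimization hit the sweep limit before converging")
        self._write_lengths_to_tree()
        return best

    def _write_lengths_to_tree(self) -> None:
        for node, length in zip(self._nodes[:-1], self.branch_lengths):
            node.length = float(length)

    # -- fast optimization via outside/inside partials ----------------------

    def _down_pass(self, lengths: np.ndarray):
        """Inside (below-node) partials for every node, with per-site scalers.

        Also returns the per-edge "lifted" partials P(t_e) @ D_e, which the
        outside pass reuses.
        """
        model = self.model
        rates = model.variable_rates()
        pmats = model.transition_matrices(lengths, rates)
        ncat = rates.size
        n_pat = self._pattern_codes.shape[1]
        down: list[np.ndarray] = [None] * len(self._nodes)
        lifted: list[np.ndarray] = [None] * len(self._nodes)
        scal: list[np.ndarray] = [None] * len(self._nodes)
        for i, children in enumerate(self._children):
            if not children:
                down[i] = np.broadcast_to(self._leaf_partials[i], (ncat, 20, n_pat))
                scal[i] = np.zeros(n_pat)
                continue
            prod = None
            s = np.zeros(n_pat)
            for c in children:
                lifted[c] = pmats[c] @ down[c]
                prod = lifted[c] if prod is None else prod * lifted[c]
                s += scal[c]
            m = np.maximum(prod.max(axis=(0, 1)), _TINY)
            prod = prod / m
            s += np.log(m)
            down[i] = prod
            scal[i] = s
        return down, lifted, scal, pmats

    def _up_pass(self, down, lifted, scal, pmats):
        """Outside partials: for each non-root node v, the likelihood of all
        data outside v's subtree given the state at v's parent (the edge
        above v excluded).  Uses reversibility, so the stationary
        frequencies are applied only in the final edge-likelihood sum."""
        n_nodes = len(self._nodes)
        up: list[np.ndarray] = [None] * n_nodes
        up_scal: list[np.ndarray] = [None] * n_nodes
        n_pat = self._pattern_codes.shape[1]
        root = n_nodes - 1
        for p in range(root, -1, -1):
            children = self._children[p]
            if not children:
                continue
            if p == root:
                above = None
                above_scal = np.zeros(n_pat)
            else:
                # data above p given state at p
                above = pmats[p] @ up[p]
                above_scal = up_scal[p]
            for v in children:
                prod = None if above is None else above
                s = above_scal
                for u in children:
                    if u == v:
                        continue
                    prod = lifted[u] if prod is None else prod * lifted[u]
                    s = s + scal[u]
                if prod is None:  # root with a single child
                    prod = np.ones_like(down[v])
                m = np.maximum(prod.max(axis=(0, 1)), _TINY)
                up[v] = prod / m
                up_scal[v] = s + np.log(m)
        return up, up_scal

    def _edge_projection(self, edge: int, down, scal, up, up_scal):
        """Eigenbasis projection of one edge's outside/inside partials.

        With P(t) = L e^{Lambda t} R the likelihood of candidate length t
        reduces to a (category x eigenvalue) x sites contraction against
        the returned weight array.
        """
        model = self.model
        weights = model.variable_weights()
        outer = weights[:, None, None] * model.frequencies[None, :, None] * up[edge]
        proj_out = model._left.T[None] @ outer
        proj_in = model._right[None] @ np.ascontiguousarray(down[edge])
        return proj_out * proj_in, scal[edge] + up_scal[edge]

    def _edge_totals_from_projection(
        self, candidates: np.ndarray, w: np.ndarray, log_scale: np.ndarray
    ) -> np.ndarray:
        model = self.model
        rates = model.variable_rates()
        expd = np.exp(
            model.eigenvalues[None, None, :]
            * (candidates[:, None, None] * rates[None, :, None])
        )  # (K, C, 20)
        site = expd.reshape(len(candidates), -1) @ w.reshape(-1, w.shape[-1])
        if model.p_inv:
            site = site + model.p_inv * self._invariant_lik * np.exp(-np.clip(log_scale, -700, 700))
        logs = np.log(np.maximum(site, _TINY)) + log_scale
        return logs @ self._pattern_counts

    def _edge_totals(self, edge: int, candidates: np.ndarray, down, scal, up, up_scal) -> np.ndarray:
        """Total logL for several candidate lengths of one edge at once."""
        w, log_scale = self._edge_projection(edge, down, scal, up, up_scal)
        return self._edge_totals_from_projection(candidates, w, log_scale)

    def optimize_fast(
        self,
        tol: float = 1e-4,
        max_sweeps: int = 10,
        n_grid: int = 11,
        span: float = 8.0,
    ) -> float:
        """Approximate branch-length optimization for pipeline-scale scoring.

        Each sweep recomputes inside/outside partials once, then line-
        searches every branch on a multiplicative grid (refined by one
        parabolic step in log-length) against partials held fixed within
        the sweep.  A full evaluation guards every sweep: if the joint
        update ever fails to improve the exact log-likelihood the sweep is
        rolled back and optimization stops.  Cheaper but coarser than
        :meth:`optimize`; intended for scoring many candidate topologies.
        """
        lengths = self.branch_lengths
        best = self.log_likelihood(lengths)
        for _ in range(max_sweeps):
            snapshot = lengths.copy()
            down, lifted, scal, pmats = self._down_pass(lengths)
            up, up_scal = self._up_pass(down, lifted, scal, pmats)
            for e in range(lengths.size):
                t = lengths[e]
                grid = np.clip(
                    t * np.logspace(-np.log10(span), np.log10(span), n_grid),
                    MIN_BRANCH_LENGTH,
                    MAX_BRANCH_LENGTH,
                )
                grid = np.unique(np.append(grid, t))
                w, log_scale = self._edge_projection(e, down, scal, up, up_scal)
                totals = self._edge_totals_from_projection(grid, w, log_scale)
                k = int(np.argmax(totals))
                # one parabolic refinement in log-length
                if 0 < k < grid.size - 1:
                    x = np.log(grid[k - 1 : k + 2])
                    y = totals[k - 1 : k + 2]
                    denom = (x[0] - x[1]) * (y[0] - y[2]) - (x[0] - x[2]) * (y[0] - y[1])
                    if abs(denom) > 1e-30:
                        num = (x[0] ** 2 - x[1] ** 2) * (y[0] - y[2]) - (
                            x[0] ** 2 - x[2] ** 2
                        ) * (y[0] - y[1])
                        cand = np.exp(num / (2 * denom))
                        if np.isfinite(cand) and MIN_BRANCH_LENGTH <= cand <= MAX_BRANCH_LENGTH:
                            t2 = self._edge_totals_from_projection(
                                np.array([cand]), w, log_scale
                            )[0]
                            if t2 > totals[k]:
                                lengths[e] = cand
                                continue
                lengths[e] = grid[k]
            now = self.log_likelihood(lengths)
            if now < best:
                lengths[:] = snapshot
                break
            gain = now - best
            best = now
            if gain < tol:
                break
        self._write_lengths_to_tree()
        return best


def site_log_likelihoods(alignment: Alignment, tree: Tree, model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihoods of the alignment on a tree with branch lengths."""
    return TreeLikelihood(alignment, tree, model).site_log_likelihoods()


def optimize_branch_lengths(
    alignment: Alignment,
    tree: Tree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
    xatol: float = 1e-6,
) -> tuple[Tree, float]:
    """ML branch lengths on a fixed topology; returns ``(tree_copy, logL)``."""
    tree = tree.copy()
    engine = TreeLikelihood(alignment, tree, model)
    logl = engine.optimize(tol=tol, max_sweeps=max_sweeps, xatol=xatol)
    return tree, logl


def estimate_alpha(
    alignment: Alignment,
    tree: Tree,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (0.05, 20.0),
    optimize_branches: bool = True,
    xatol: float = 1e-3,
) -> float:
    """Gamma-shape estimate maximizing logL on the given topology.

    When ``optimize_branches`` is set the branch lengths are refitted for
    each candidate alpha (slower, less biased); otherwise the tree's current
    lengths are held fixed.
    """

    def neg(log_alpha: float) -> float:
        m = model.with_params(alpha=float(np.exp(log_alpha)))
        if optimize_branches:
            _, logl = optimize_branch_lengths(alignment, tree, m, tol=1e-4, xatol=1e-4)
        else:
            logl = float(
                TreeLikelihood(alignment, tree, m).log_likelihood()
            )
        return -logl

    res = minimize_scalar(
        neg,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(np.exp(res.x))
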