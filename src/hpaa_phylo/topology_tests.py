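"""RELL bootstrap probabilities and KH/SH topology tests.

Given per-site log-likelihoods for a set of candidate topologies, the RELL
(resampling of estimated log-likelihoods) bootstrap resamples site columns
multinomially — without re-optimizing any tree — and asks how often each
topology attains the maximal resampled total.  The one-sided
Kishino-Hasegawa test compares each topology against the maximum-likelihood
one through the centered resampled distribution of the log-likelihood
difference; the Shimodaira-Hasegawa test does the same simultaneously over
the whole candidate set, which makes it conservative (SH p >= KH p on
shared resamples).  By the usual convention the ML topology itself reports
p = 1.00 in both tests.

Clade support for a leaf group is the summed RELL BP of the topologies in
which the group forms a bipartition — the statistic used to quantify
support for the exclusive lamprey EmxA-EmxB grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo_core import Alignment, SubstitutionModel, Tree, TreeLikelihood

__all__ = [
    "SiteLogLikelihoodMatrix",
    "score_topologies",
    "rell_bootstrap",
    "kh_test",
    "sh_test",
    "topology_test_table",
    "clade_support",
]


@dataclass
class SiteLogLikelihoodMatrix:
    """Topologies x sites matrix of per-site log-likelihoods."""

    matrix: np.ndarray
    topologies: list[Tree] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("site log-likelihood matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("site log-likelihoods must be finite")

    @property
    def n_topologies(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.matrix).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_tsv(cls, path) -> "SiteLogLikelihoodMatrix":
        return cls(pd.read_csv(path, sep="\t", header=None).to_numpy())


def score_topologies(
    alignment: Alignment,
    topologies: list[Tree],
    model: SubstitutionModel,
    tol: float = 1e-4,
    max_sweeps: int = 10,
    exact: bool = False,
    xatol: float = 1e-6,
) -> SiteLogLikelihoodMatrix:
    """Optimize branch lengths and collect per-site logL for each topology.

    The default grid-accelerated optimizer is what makes exhaustive scans
    over a hundred topologies affordable; ``exact=True`` switches to the
    slower per-branch Brent optimizer with tolerance ``xatol``.
    """
    rows = []
    fitted = []
    for topo in topologies:
        tree = topo.copy()
        engine = TreeLikelihood(alignment, tree, model)
        if exact:
            engine.optimize(tol=tol, xatol=xatol)
        else:
            engine.optimize_fast(tol=tol, max_sweeps=max_sweeps)
        rows.append(engine.site_log_likelihoods())
        fitted.append(tree)
    return SiteLogLikelihoodMatrix(np.vstack(rows), fitted)


def _resampled_totals(
    matrix: np.ndarray, n_replicates: int, seed: int
) -> np.ndarray:
    """Multinomial RELL resampled totals, shape (n_replicates, n_topologies)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if seed is None:
        raise ValueError("a seed is required for reproducible resampling")
    n_sites = matrix.shape[1]
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites), size=n_replicates)
    return weights.astype(float) @ matrix.T


def rell_bootstrap(
    matrix: SiteLogLikelihoodMatrix | np.ndarray,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """RELL bootstrap probability of each topology being the best.

    Ties in the resampled maximum are split equally among the tied
    topologies, so the BPs sum to exactly 1.
    """
    m = matrix.matrix if isinstance(matrix, SiteLogLikelihoodMatrix) else np.asarray(matrix, float)
    if m.shape[0] == 1:
        return np.array([1.0])
    totals = _resampled_totals(m, n_replicates, seed)
    is_max = totals >= totals.max(axis=1, keepdims=True)
    shares = is_max / is_max.sum(axis=1, keepdims=True)
    return shares.mean(axis=0)


def kh_test(
    matrix: SiteLogLikelihoodMatrix | np.ndarray,
    topology_index: int,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> float:
    """One-sided Kishino-Hasegawa p for one topology against the ML one."""
    m = matrix.matrix if isinstance(matrix, SiteLogLikelihoodMatrix) else np.asarray(matrix, float)
    kh, _ = _kh_sh(m, n_replicates, seed)
    return float(kh[topology_index])


def sh_test(
    matrix: SiteLogLikelihoodMatrix | np.ndarray,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Shimodaira-Hasegawa p for every topology (simultaneous test)."""
    m = matrix.matrix if isinstance(matrix, SiteLogLikelihoodMatrix) else np.asarray(matrix, float)
    _, sh = _kh_sh(m, n_replicates, seed)
    return sh


def _kh_sh(m: np.ndarray, n_replicates: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """KH and SH p-values from one shared set of RELL resamples.

    Sharing the resamples guarantees the documented dominance SH p >= KH p;
    the ML topology reports exactly 1.0 in both tests.
    """
    if m.shape[0] < 2:
        raise ValueError("topology tests need at least two topologies")
    totals_obs = m.sum(axis=1)
    best = int(np.argmax(totals_obs))
    deltas = totals_obs[best] - totals_obs
    resampled = _resampled_totals(m, n_replicates, seed)  # (R, T)
    centered = resampled - resampled.mean(axis=0, keepdims=True)
    kh = np.empty(m.shape[0])
    sh = np.empty(m.shape[0])
    sh_max = centered.max(axis=1)
    for t in range(m.shape[0]):
        if t == best:
            kh[t] = sh[t] = 1.0
            continue
        diff = centered[:, best] - centered[:, t]
        kh[t] = np.mean(diff >= deltas[t])
        sh[t] = np.mean(sh_max - centered[:, t] >= deltas[t])
    return kh, sh


def topology_test_table(
    matrix: SiteLogLikelihoodMatrix,
    n_replicates: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ranked summary mirroring the standard exhaustive-ML report.

    Columns: rank, topology (Newick), logL, delta_logL, se, kh_p, sh_p, bp.
    The standard error of each delta logL is the usual KH site-wise
    estimate sqrt(n * var(per-site differences)).
    """
    m = matrix.matrix
    totals = m.sum(axis=1)
    best = int(np.argmax(totals))
    n_sites = m.shape[1]
    bp = rell_bootstrap(matrix, n_replicates, seed)
    kh, sh = _kh_sh(m, n_replicates, seed)
    se = np.sqrt(n_sites * np.var(m[best] - m, axis=1, ddof=1)) if n_sites > 1 else np.zeros(len(totals))
    table = pd.DataFrame(
        {
            "topology": [t.to_newick(with_lengths=False) for t in matrix.topologies]
            if matrix.topologies
            else [str(i) for i in range(len(totals))],
            "logL": totals,
            "delta_logL": totals[best] - totals,
            "se": se,
            "kh_p": kh,
            "sh_p": sh,
            "bp": bp,
        }
    )
    table = table.sort_values("logL", ascending=False, kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def clade_support(bp, topologies: list[Tree], clade) -> float:
    """Summed RELL BP of the topologies containing ``clade`` as a bipartition."""
    bp = np.asarray(bp, dtype=float)
    if len(bp) != len(topologies):
        raise ValueError("BP vector and topology list differ in length")
    clade = frozenset(clade)
    return float(sum(p for p, t in zip(bp, topologies) if t.has_bipartition(clade)))
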