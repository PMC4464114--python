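"""Amino-acid substitution model: JTT with +G, +I and +F variants.

The model is a time-reversible 20-state Markov process.  The embedded JTT
exchangeabilities ``s_ij`` combine with stationary frequencies ``pi_j`` to
give rates ``q_ij = s_ij * pi_j``; the generator is scaled so the expected
number of substitutions per unit branch length is 1.  Rate heterogeneity
across sites uses Yang's discrete-gamma approximation: ``ncat``
equal-probability categories, each represented by its conditional mean,
with mean rate exactly 1.  An optional proportion of invariant sites
``p_inv`` adds a zero-rate class; the variable-class rates are rescaled by
``1/(1 - p_inv)`` so the overall mean rate stays 1.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammainc

from .._jtt import AA_ORDER, JTT_FREQUENCIES, JTT_LOWER_TRIANGLE

__all__ = ["AA_ORDER", "SubstitutionModel", "discretize_gamma"]

N_STATES = 20
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def discretize_gamma(alpha: float, ncat: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (conditional means).

    The gamma density has shape ``alpha`` and mean 1.  Category boundaries
    are the ``i/ncat`` quantiles; each category rate is the mean of the
    density restricted to its bin, so the rates average exactly 1 and are
    increasing in category index.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    if ncat < 1:
        raise ValueError("ncat must be at least 1")
    if ncat == 1:
        return np.ones(1)
    # quantile cut points of Gamma(alpha, scale=1/alpha)
    probs = np.arange(1, ncat) / ncat
    cuts = stats.gamma.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # mean over each bin: alpha/alpha * [I(alpha+1, a*b_hi) - I(alpha+1, a*b_lo)] * ncat
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1.0, alpha * bounds[1:]))
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = ncat * (upper - lower)
    return rates / rates.mean()  # exact renormalization against quadrature error


def _jtt_exchangeabilities() -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = JTT_LOWER_TRIANGLE[k]
            k += 1
    return s


class SubstitutionModel:
    """JTT substitution model with optional +G (gamma), +I and +F terms.

    Parameters
    ----------
    frequencies:
        ``None`` for the model's own stationary frequencies, or a length-20
        vector (in the order ``AA_ORDER``) of empirical frequencies (+F).
        A small pseudocount keeps every frequency positive.
    alpha:
        Discrete-gamma shape; ``None`` disables rate heterogeneity.
    ncat:
        Number of gamma categories (default 4).
    p_inv:
        Proportion of invariant sites; ``None`` or 0 disables +I.
    """

    name = "JTT"

    def __init__(
        self,
        frequencies: np.ndarray | None = None,
        alpha: float | None = None,
        ncat: int = 4,
        p_inv: float | None = None,
    ) -> None:
        if frequencies is None:
            freqs = np.array(JTT_FREQUENCIES, dtype=float)
        else:
            freqs = np.asarray(frequencies, dtype=float) + 1e-6
        if freqs.shape != (N_STATES,):
            raise ValueError("frequencies must be a length-20 vector")
        self.frequencies = freqs / freqs.sum()
        if p_inv is not None and not (0.0 <= p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        self.alpha = alpha
        self.ncat = int(ncat)
        self.p_inv = float(p_inv) if p_inv else 0.0
        self._build_generator()
        self._build_rate_classes()

    def _build_generator(self) -> None:
        pi = self.frequencies
        s = _jtt_exchangeabilities()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # scale to one expected substitution per unit time
        mu = -np.dot(pi, np.diag(q))
        q /= mu
        self.rate_matrix = q
        # eigendecomposition through the symmetrized generator for stability
        sqrt_pi = np.sqrt(pi)
        sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = (sym + sym.T) / 2.0
        eigvals, vecs = np.linalg.eigh(sym)
        self.eigenvalues = eigvals
        self._left = vecs / sqrt_pi[:, None]       # D^{-1/2} U
        self._right = (vecs * sqrt_pi[:, None]).T  # U' D^{1/2}

    # -- rate classes -------------------------------------------------------

    def _build_rate_classes(self) -> None:
        rates = discretize_gamma(self.alpha, self.ncat) if self.alpha is not None else np.ones(1)
        if self.p_inv:
            rates = rates / (1.0 - self.p_inv)
        self._var_rates = rates
        self._var_weights = np.full(rates.size, (1.0 - self.p_inv) / rates.size)

    def variable_rates(self) -> np.ndarray:
        """Rates of the variable (gamma) classes, rescaled for +I."""
        return self._var_rates

    def variable_weights(self) -> np.ndarray:
        return self._var_weights

    def with_params(self, alpha: float | None = None, p_inv: float | None = None) -> "SubstitutionModel":
        """Copy of the model with alpha and/or p_inv replaced."""
        out = SubstitutionModel.__new__(SubstitutionModel)
        out.__dict__.update(self.__dict__)
        if alpha is not None:
            out.alpha = alpha
        if p_inv is not None:
            out.p_inv = float(p_inv)
        out._build_rate_classes()
        return out

    # -- transition probabilities ------------------------------------------

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for a single branch length."""
        return self.transition_matrices(np.array([t]), np.ones(1))[0, 0]

    def transition_matrices(self, lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """Batch of transition matrices, shape (n_edges, n_rates, 20, 20)."""
        lt = lengths[:, None, None] * rates[None, :, None]  # (E, C, 1)
        expd = np.exp(self.eigenvalues[None, None, :] * lt)  # (E, C, 20)
        p = (self._left[None, None] * expd[:, :, None, :]) @ self._right
        np.maximum(p, 0.0, out=p)
        return p

    def encode(self, sequence: str) -> np.ndarray:
        """Integer state codes for a sequence; non-standard letters become -1."""
        return np.array([AA_INDEX.get(ch, -1) for ch in sequence.upper()], dtype=np.int16)
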