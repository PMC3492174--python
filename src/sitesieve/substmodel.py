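"""Reversible substitution models (GTR+Gamma family, nucleotide or protein).

The rate matrix is built as Q_ij = s_ij * pi_j (i != j) from symmetric
exchangeabilities s and stationary frequencies pi, then scaled to one
expected substitution per site per unit branch length.  Transition
probabilities come from the eigendecomposition of the pi-symmetrized
matrix, which also vectorizes cleanly over sites and rate categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["SubstitutionModel", "discrete_gamma_rates", "transition_matrix"]

NT_STATES = "ACGT"
AA_STATES = "ACDEFGHIKLMNPQRSTVWY"


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-one discrete Gamma category rates (mean of each quantile bin)."""
    if k == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X; a<X<b] for Gamma(alpha, 1/alpha) uses the shape alpha+1 CDF
    upper = gamma_dist.cdf(edges[1:], a=alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(edges[:-1], a=alpha + 1, scale=1.0 / alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


def _exchange_matrix(exchangeabilities: np.ndarray, n: int) -> np.ndarray:
    s = np.asarray(exchangeabilities, dtype=float)
    if s.ndim == 1:
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        if len(s) != len(iu[0]):
            raise ValueError(
                f"need {len(iu[0])} exchangeabilities for {n} states, got {len(s)}"
            )
        m[iu] = s
        m += m.T
        return m
    if s.shape != (n, n) or not np.allclose(s, s.T):
        raise ValueError("exchangeability matrix must be symmetric n x n")
    return s


@dataclass
class SubstitutionModel:
    """A reversible Markov substitution model with optional Gamma rates.

    Parameters
    ----------
    exchangeabilities : array
        Upper-triangle vector (AC, AG, AT, CG, CT, GT for nucleotides) or a
        full symmetric matrix; nonnegative.
    freqs : array
        Stationary frequencies on the simplex.
    alpha : float or None
        Gamma shape for among-site rate variation; None disables it.
    n_cats : int
        Number of discrete Gamma categories (ignored when alpha is None).
    """

    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float | None = None
    n_cats: int = 4
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        n = self.n_states
        if len(self.freqs) != n:
            raise ValueError(f"expected {n} frequencies, got {len(self.freqs)}")
        if np.any(self.freqs < 0) or abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must be a simplex vector")
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be nonnegative")

    @property
    def n_states(self) -> int:
        return 4 if self.alphabet == "nt" else 20

    @property
    def states(self) -> str:
        return NT_STATES if self.alphabet == "nt" else AA_STATES

    @classmethod
    def jc(cls, alpha: float | None = None, n_cats: int = 4) -> "SubstitutionModel":
        return cls(np.ones(6), np.full(4, 0.25), alpha, n_cats, "nt")

    @classmethod
    def gtr(cls, exchangeabilities, freqs, alpha: float | None = None,
            n_cats: int = 4) -> "SubstitutionModel":
        return cls(np.asarray(exchangeabilities, float), np.asarray(freqs, float),
                   alpha, n_cats, "nt")

    @classmethod
    def aa_equal(cls, freqs=None, alpha: float | None = None,
                 n_cats: int = 4) -> "SubstitutionModel":
        """Poisson-style protein model (equal exchangeabilities)."""
        freqs = np.full(20, 0.05) if freqs is None else np.asarray(freqs, float)
        return cls(np.ones(190), freqs, alpha, n_cats, "aa")

    @classmethod
    def aa_from_table(cls, path, alpha: float | None = None,
                      n_cats: int = 4) -> "SubstitutionModel":
        """Load a PAML-style protein table: 19 lower-triangle exchangeability
        rows followed by a line of 20 frequencies."""
        values: list[float] = []
        for line in open(path):
            values.extend(float(x) for x in line.split())
        if len(values) != 190 + 20:
            raise ValueError("expected 190 exchangeabilities + 20 frequencies")
        m = np.zeros((20, 20))
        k = 0
        for i in range(1, 20):
            for j in range(i):
                m[i, j] = m[j, i] = values[k]
                k += 1
        freqs = np.array(values[190:])
        return cls(m, freqs / freqs.sum(), alpha, n_cats, "aa")

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_cats)

    def rate_matrix(self, freqs_override=None) -> np.ndarray:
        """Normalized generator Q (rows sum to 0, expected rate 1)."""
        pi = self.freqs if freqs_override is None else np.asarray(freqs_override, float)
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must be a simplex vector")
        n = self.n_states
        s = _exchange_matrix(self.exchangeabilities, n)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return q / mu

    def eigensystem(self, freqs_override=None):
        """(eigenvalues, U, U^-1) of Q via pi-symmetrization, so that
        P(t) = U diag(exp(lambda t)) U^-1."""
        pi = self.freqs if freqs_override is None else np.asarray(freqs_override, float)
        q = self.rate_matrix(freqs_override)
        d = np.sqrt(np.clip(pi, 1e-300, None))
        b = (q * d[:, None]) / d[None, :]
        lam, v = np.linalg.eigh((b + b.T) / 2.0)
        u = v / d[:, None]
        uinv = v.T * d[None, :]
        return lam, u, uinv


def transition_matrix(model: SubstitutionModel, t: float,
                      freqs_override=None) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    lam, u, uinv = model.eigensystem(freqs_override)
    p = (u * np.exp(lam * t)[None, :]) @ uinv
    return np.clip(p, 0.0, None)
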