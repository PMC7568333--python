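"""Amino-acid substitution models shared by the simulator and the likelihood.

Models are time-reversible 20-state CTMCs normalised to one expected
substitution per unit branch length, so branch lengths are always in expected
substitutions per site.  Two exchangeability sets are provided: "poisson"
(equal rates, equal frequencies) and "lg" (the LG empirical matrix with its
empirical frequencies).

Site-rate heterogeneity uses the discrete-gamma approximation with
equal-probability categories, each category carrying the mean rate of its
quantile bin; rates average to 1 by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .data.lg import AA_ORDER, LG_EXCH, LG_FREQS

N_STATES = 20


class SubstModel:
    """Reversible rate matrix with spectral transition-probability evaluation."""

    def __init__(self, name: str, exchangeabilities: np.ndarray, freqs: np.ndarray):
        self.name = name
        self.freqs = np.asarray(freqs, dtype=float)
        self.freqs = self.freqs / self.freqs.sum()
        S = np.asarray(exchangeabilities, dtype=float)
        Q = S * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise: expected rate sum_i pi_i * (-Q_ii) = 1
        mean_rate = -(self.freqs * np.diag(Q)).sum()
        Q /= mean_rate
        self.Q = Q
        # symmetrise with pi^(1/2) for a stable eigendecomposition
        sq = np.sqrt(self.freqs)
        B = (Q / sq[None, :]) * sq[:, None]
        B = (B + B.T) / 2.0
        evals, U = np.linalg.eigh(B)
        self.evals = evals
        self._A = U / sq[:, None]  # D^{-1/2} U
        self._B = (U * sq[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) with t in expected substitutions per site."""
        if t < 0:
            raise ValueError("negative branch length")
        P = (self._A * np.exp(self.evals * t)) @ self._B
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of branch lengths, shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        if ts.min() < 0:
            raise ValueError("negative branch length")
        E = np.exp(ts[:, None] * self.evals[None, :])  # (m, 20)
        P = (self._A[None, :, :] * E[:, None, :]) @ self._B
        np.clip(P, 0.0, None, out=P)
        return P


def poisson_model() -> SubstModel:
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return SubstModel("poisson", S, np.full(N_STATES, 1.0 / N_STATES))


def lg_model() -> SubstModel:
    return SubstModel("lg", LG_EXCH, LG_FREQS)


def get_model(name: str) -> SubstModel:
    name = name.lower()
    if name == "poisson":
        return poisson_model()
    if name == "lg":
        return lg_model()
    raise ValueError(f"unknown substitution model {name!r}")


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete-gamma categories (mean 1)."""
    if k == 1:
        return np.ones(1)
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # mean of X in (a, b] for X~Gamma(shape, 1/shape):
    # k * (I(b*shape; shape+1) - I(a*shape; shape+1)) with regularised I
    upper = gammainc(shape + 1, bounds[1:] * shape)
    lower = gammainc(shape + 1, bounds[:-1] * shape)
    rates = k * (upper - lower)
    return rates / rates.mean()


def p_same_equal_rates(nu: float) -> float:
    """P(identical residues) for the 20-state equal-rates chain at distance nu."""
    return 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * nu / 19.0)


__all__ = [
    "AA_ORDER",
    "SubstModel",
    "poisson_model",
    "lg_model",
    "get_model",
    "discrete_gamma_rates",
    "p_same_equal_rates",
]
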