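"""Reversible amino-acid substitution models and discrete-gamma rate heterogeneity.

A model is (S, pi, alpha, K): symmetric exchangeabilities, equilibrium
frequencies, gamma shape, and the number of equal-probability rate
categories. Q is built as q_ij = S_ij * pi_j and normalized to one expected
replacement per site per unit branch length. The default empirical model is
LG, read from a bundled PAML dat-style file; a Poisson model (uniform
everything) is built in for controlled tests, and models over reduced
alphabets are supported so small instances can be checked by enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACIDS

__all__ = [
    "SubstitutionModel",
    "RateMatrix",
    "build_rate_matrix",
    "discrete_gamma_rates",
    "load_paml_dat",
    "lg_model",
    "poisson_model",
    "halophilic_frequencies",
]


class ModelError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    S: np.ndarray  # symmetric exchangeabilities, zero diagonal
    pi: np.ndarray  # equilibrium frequencies
    alpha: float = 1.0  # gamma shape for among-site rate variation
    K: int = 4  # number of discrete gamma categories
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k = len(self.alphabet)
        if self.S.shape != (k, k):
            raise ModelError(f"S must be {k}x{k}")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ModelError("S is not symmetric")
        off = self.S[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ModelError("negative exchangeability")
        if self.pi.shape != (k,):
            raise ModelError("pi has wrong length")
        if np.any(self.pi <= 0):
            raise ModelError("zero or negative equilibrium frequency")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ModelError("pi does not sum to 1")
        if not self.alpha > 0:
            raise ModelError("alpha must be positive")
        if self.K < 1:
            raise ModelError("K must be >= 1")

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def state_index(self, symbol: str) -> int:
        return self.alphabet.index(symbol)

    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.K)

    def with_frequencies(self, pi: np.ndarray) -> "SubstitutionModel":
        """Same exchangeabilities under different equilibrium frequencies."""
        return SubstitutionModel(self.S, pi, self.alpha, self.K, self.alphabet)


@dataclass
class RateMatrix:
    Q: np.ndarray
    norm: float  # divisor applied so that -sum_i pi_i q_ii == 1
    pi: np.ndarray
    # eigendecomposition of the symmetrized matrix, for fast exp(Qt)
    _evals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are conditional distributions of the child state."""
        if t < 0:
            raise ModelError("negative branch length")
        if t == 0:
            return np.eye(len(self.pi))
        P = (self._right * np.exp(self._evals * t)) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def build_rate_matrix(model: SubstitutionModel) -> RateMatrix:
    """q_ij = S_ij pi_j (i != j); diagonal closes rows; scaled to rate 1.

    Detailed balance pi_i q_ij = pi_j q_ji follows from the symmetry of S.
    """
    pi = model.pi
    Q = model.S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    norm = -(pi * np.diag(Q)).sum()
    if norm <= 0:
        raise ModelError("degenerate model: zero expected rate")
    Q = Q / norm
    # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    evals, U = np.linalg.eigh((B + B.T) / 2.0)
    right = U / sq[:, None] * 1.0
    left = U.T * sq[None, :]
    return RateMatrix(Q=Q, norm=norm, pi=pi, _evals=evals, _left=left, _right=right)


def discrete_gamma_rates(alpha: float, K: int) -> np.ndarray:
    """K equal-probability categories; the category rate is the mean of its
    quantile bin of Gamma(alpha, mean 1). Rates ascend and average to 1."""
    if not alpha > 0:
        raise ModelError("alpha must be positive")
    if K < 1:
        raise ModelError("K must be >= 1")
    if K == 1:
        return np.ones(1)
    dist = gamma_dist(a=alpha, scale=1.0 / alpha)
    upper = gamma_dist(a=alpha + 1.0, scale=1.0 / alpha)
    bounds = dist.ppf(np.arange(K + 1) / K)
    # mean over a bin: E[X; l<X<u] / P(bin) with E[X; .] = F_{a+1}(u) - F_{a+1}(l)
    mass = np.diff(upper.cdf(bounds))
    rates = mass * K
    rates /= rates.mean()
    return rates


# ---------------------------------------------------------------------------
# bundled / built-in models


def load_paml_dat(path_or_text: str, alpha: float = 1.0, K: int = 4) -> SubstitutionModel:
    """Read a PAML dat-style empirical model: 19 lines of lower-triangle
    exchangeabilities followed by the 20 equilibrium frequencies."""
    if "\n" in path_or_text:
        text = path_or_text
    else:
        with open(path_or_text) as fh:
            text = fh.read()
    values = [float(tok) for tok in text.split()]
    if len(values) < 190 + 20:
        raise ModelError("dat file too short: need 190 exchangeabilities + 20 frequencies")
    tri, freqs = values[:190], values[190:210]
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = tri[k]
            k += 1
    pi = np.array(freqs)
    pi = pi / pi.sum()
    return SubstitutionModel(S, pi, alpha, K)


def lg_model(alpha: float = 1.0, K: int = 4) -> SubstitutionModel:
    """The LG empirical replacement model (default model of the pipeline)."""
    text = resources.files("haloasr.data").joinpath("lg.dat").read_text()
    return load_paml_dat(text, alpha=alpha, K=K)


def poisson_model(alpha: float = 1.0, K: int = 4, alphabet: str = AMINO_ACIDS) -> SubstitutionModel:
    """Equal exchangeabilities, uniform frequencies (Poisson / JC-like)."""
    k = len(alphabet)
    S = np.ones((k, k))
    np.fill_diagonal(S, 0.0)
    return SubstitutionModel(S, np.full(k, 1.0 / k), alpha, K, alphabet)


def halophilic_frequencies(
    base_pi: np.ndarray | None = None,
    de_total: float = 0.22,
    kr_total: float = 0.06,
) -> np.ndarray:
    """Acidic-biased stationary composition emulating halophilic proteomes.

    D+E mass is pinned to ``de_total`` and K+R to ``kr_total`` (split within
    each pair proportionally to the base model); the remaining mass is spread
    over the other 16 residues proportionally to the base frequencies.
    """
    if base_pi is None:
        base_pi = lg_model().pi
    base_pi = np.asarray(base_pi, dtype=float)
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    de = [idx["D"], idx["E"]]
    kr = [idx["K"], idx["R"]]
    rest = [i for i in range(20) if i not in de + kr]
    pi = np.empty(20)
    pi[de] = de_total * base_pi[de] / base_pi[de].sum()
    pi[kr] = kr_total * base_pi[kr] / base_pi[kr].sum()
    rest_total = 1.0 - de_total - kr_total
    pi[rest] = rest_total * base_pi[rest] / base_pi[rest].sum()
    return pi / pi.sum()
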