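"""Empirical amino-acid substitution models and +I+Gamma rate mixtures.

A :class:`SubstitutionModel` couples a symmetric exchangeability matrix S
with equilibrium frequencies pi to form the reversible rate matrix
Q_ij = S_ij * pi_j (i != j), normalized to one expected substitution per
site per unit branch length.  Transition matrices P(t) = expm(Q t r) are
computed through the symmetric eigendecomposition of the
pi^{1/2}-similarity transform, so a single decomposition serves every
(branch length, rate) combination.

Rate heterogeneity follows the standard discrete-gamma treatment: K
equal-probability categories represented by their class means, optionally
combined with a zero-rate invariant class of weight p_inv.  When p_inv > 0
the gamma rates are inflated by 1/(1 - p_inv) so the mixture mean stays 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import gammainc, gammaincinv

from .alignment import AA_ORDER, GAP_CODE

N_STATES = 20

#: Names of the shipped empirical exchangeability matrices.
EMPIRICAL_MODELS = ("WAG", "LG", "JTT", "Dayhoff")


def _load_dat(name: str):
    text = resources.files("carasr.data").joinpath(f"{name.lower()}.dat").read_text()
    rows = [
        [float(x) for x in line.split()]
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    tri, freqs = rows[:-1], rows[-1]
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(tri, start=1):
        S[i, : len(row)] = row
        S[: len(row), i] = row
    return S, np.asarray(freqs)


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible 20-state CTMC model of amino-acid substitution."""

    name: str
    S: np.ndarray  # symmetric exchangeabilities, zero diagonal
    pi: np.ndarray  # equilibrium frequencies, sums to 1

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape != (N_STATES, N_STATES) or pi.shape != (N_STATES,):
            raise ValueError("model matrices must be 20x20 / length-20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
            raise ValueError("equilibrium frequencies must be a distribution")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "pi", pi / pi.sum())

    @property
    def Q(self) -> np.ndarray:
        """Rate matrix, rows summing to 0, mean rate 1."""
        Q = self.S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(self.pi * np.diag(Q)).sum()
        return Q / mean_rate

    def _eig(self):
        """Eigendecomposition of the symmetrized rate matrix (cached)."""
        cache = getattr(self, "_eig_cache", None)
        if cache is None:
            sq = np.sqrt(self.pi)
            B = (sq[:, None] * self.Q) / sq[None, :]
            B = (B + B.T) / 2.0  # symmetric up to round-off
            lam, V = np.linalg.eigh(B)
            left = V.T * sq[None, :]  # V' diag(sqrt pi)
            right = (1.0 / sq)[:, None] * V  # diag(1/sqrt pi) V
            cache = (lam, right, left)
            object.__setattr__(self, "_eig_cache", cache)
        return cache

    def transition_matrix(self, t: float, r: float = 1.0) -> np.ndarray:
        """P(t, r) = expm(Q * t * r); rows sum to 1."""
        if t < 0 or r < 0:
            raise ValueError("branch length and rate must be >= 0")
        lam, right, left = self._eig()
        P = (right * np.exp(lam * t * r)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def transition_tensor(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t, r_i) for a vector of rates, shape (n, 20, 20)."""
        lam, right, left = self._eig()
        E = np.exp(np.multiply.outer(np.asarray(rates, dtype=float) * t, lam))
        P = np.einsum("il,sl,lj->sij", right, E, left)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)

    def with_frequencies(self, pi: np.ndarray, suffix: str = "+F") -> "SubstitutionModel":
        return SubstitutionModel(self.name + suffix, self.S, np.asarray(pi, float))


def get_model(name: str) -> SubstitutionModel:
    """Load a shipped model by name (WAG, LG, JTT, Dayhoff, Poisson)."""
    if name.lower() == "poisson":
        S = np.ones((N_STATES, N_STATES))
        np.fill_diagonal(S, 0.0)
        return SubstitutionModel("Poisson", S, np.full(N_STATES, 1.0 / N_STATES))
    if name not in EMPIRICAL_MODELS:
        raise KeyError(f"unknown model {name!r}; available: {EMPIRICAL_MODELS + ('Poisson',)}")
    S, pi = _load_dat(name)
    return SubstitutionModel(name, S, pi)


def alignment_frequencies(msa, pseudocount: float = 1.0) -> np.ndarray:
    """Residue frequencies over all non-gap characters with +1 smoothing.

    ``X`` contributes to occupancy but not to any residue count.
    """
    codes = msa.codes()
    counts = np.bincount(codes[codes < N_STATES].ravel(), minlength=N_STATES).astype(float)
    counts += pseudocount
    return counts / counts.sum()


def discretize_gamma(alpha: float, K: int) -> np.ndarray:
    """Class means of the K equal-probability categories of Gamma(alpha, rate=alpha).

    The mean-1 gamma distribution is cut at its K-quantiles and each class is
    represented by its conditional mean, so the category rates average to 1.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("gamma shape alpha must be positive and finite")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones(1)
    # class boundaries in units of the (shape=alpha, rate=alpha) distribution
    qs = gammaincinv(alpha, np.arange(1, K) / K) / alpha
    edges = np.concatenate([[0.0], qs, [np.inf]])
    # conditional class mean via the regularized incomplete gamma of shape alpha+1
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    rates = K * (upper - lower)
    return rates


@dataclass(frozen=True)
class RateMixture:
    """Across-site rate mixture: K discrete-gamma categories + invariant class.

    ``rates``/``weights`` include the zero-rate invariant class (first entry
    when ``p_inv > 0``) and satisfy sum(w) = 1 and sum(w * r) = 1.
    """

    alpha: float
    p_inv: float
    K: int
    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, float)
        w = np.asarray(self.weights, float)
        if not np.isclose(w.sum(), 1.0, atol=1e-10):
            raise ValueError("mixture weights must sum to 1")
        if not np.isclose((w * r).sum(), 1.0, atol=1e-10):
            raise ValueError("mixture mean rate must be 1")
        if (r < 0).any():
            raise ValueError("category rates must be >= 0")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)

    @classmethod
    def gamma(cls, alpha: float = 1.0, K: int = 8, p_inv: float = 0.0) -> "RateMixture":
        if not (0.0 <= p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        g = discretize_gamma(alpha, K)
        if p_inv > 0:
            rates = np.concatenate([[0.0], g / (1.0 - p_inv)])
            weights = np.concatenate([[p_inv], np.full(K, (1.0 - p_inv) / K)])
        else:
            rates = g
            weights = np.full(K, 1.0 / K)
        return cls(alpha, p_inv, K, rates, weights)

    @classmethod
    def single_rate(cls) -> "RateMixture":
        return cls.gamma(alpha=1.0, K=1, p_inv=0.0)
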