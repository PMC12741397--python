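"""GTR-family nucleotide substitution models with +I and discrete-Gamma rates.

Base order is A, C, G, T throughout.  The rate matrix is normalised so the
expected substitution rate at stationarity is 1 (branch lengths are expected
substitutions per site).  Rate heterogeneity is the usual mixture: an optional
invariant class (rate 0, weight ``p_inv``) plus ``ncat`` equal-weight Gamma
categories using category means (Yang's discretisation), rescaled so the
mixture mean stays 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["SubstModel", "transition_matrix", "BASES", "BASE_INDEX"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# pair order for the 6 exchangeabilities: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class SubstModel:
    """GTR(+I)+Gamma substitution model.

    Parameters
    ----------
    rates : 6 exchangeabilities in order AC, AG, AT, CG, CT, GT.
    freqs : stationary base frequencies (A, C, G, T), must sum to 1.
    p_inv : proportion of invariant sites in [0, 1).
    alpha : Gamma shape; ignored when ``ncat == 1``.
    ncat  : number of discrete Gamma categories (>= 1).
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    p_inv: float = 0.0
    alpha: float = 1.0
    ncat: int = 1

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates < 0):
            raise ValueError("need 6 non-negative exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError(f"base frequencies sum to {self.freqs.sum()}, not 1")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")
        self._decomp = None
        self._mixture = None

    # ------------------------------------------------------------ constructors
    @classmethod
    def jc(cls, ncat: int = 1, alpha: float = 1.0, p_inv: float = 0.0) -> "SubstModel":
        return cls(np.ones(6), np.full(4, 0.25), p_inv, alpha, ncat)

    @classmethod
    def hky(cls, kappa: float, freqs=None, p_inv: float = 0.0,
            alpha: float = 1.0, ncat: int = 1) -> "SubstModel":
        """HKY85: transitions (AG, CT) scaled by kappa relative to transversions."""
        r = np.ones(6)
        r[1] = kappa  # AG
        r[4] = kappa  # CT
        if freqs is None:
            freqs = np.full(4, 0.25)
        return cls(r, np.asarray(freqs, dtype=float), p_inv, alpha, ncat)

    # ---------------------------------------------------------------- matrices
    def q_matrix(self) -> np.ndarray:
        """Normalised GTR rate matrix (rows sum to 0, mean rate 1)."""
        Q = np.zeros((4, 4))
        for s, (i, j) in zip(self.rates, _PAIRS):
            Q[i, j] = s * self.freqs[j]
            Q[j, i] = s * self.freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(self.freqs * np.diag(Q)).sum()
        return Q / mu

    def decomposition(self):
        """Cached symmetric eigendecomposition: P(t) = V exp(L t) Vinv."""
        if self._decomp is None:
            Q = self.q_matrix()
            sp = np.sqrt(self.freqs)
            B = (Q * sp[:, None]) / sp[None, :]  # diag(sp) Q diag(1/sp)
            B = 0.5 * (B + B.T)
            lam, U = np.linalg.eigh(B)
            V = U / sp[:, None]
            Vinv = U.T * sp[None, :]
            self._decomp = (lam, V, Vinv)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrix(self, t)

    def mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(category rates, weights); mixture mean is exactly 1 (cached)."""
        if self._mixture is not None:
            return self._mixture
        if self.ncat == 1:
            gam = np.array([1.0])
        else:
            gam = _gamma_category_means(self.alpha, self.ncat)
        wg = np.full(self.ncat, (1.0 - self.p_inv) / self.ncat)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], gam / (1.0 - self.p_inv)])
            weights = np.concatenate([[self.p_inv], wg])
        else:
            rates, weights = gam, wg
        self._mixture = (rates, weights)
        return rates, weights

    def stationary_sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(4, size=n, p=self.freqs)


from functools import lru_cache


@lru_cache(maxsize=4096)
def _gamma_category_means_cached(alpha: float, k: int) -> tuple:
    return tuple(_gamma_category_means_impl(alpha, k))


def _gamma_category_means(alpha: float, k: int) -> np.ndarray:
    return np.array(_gamma_category_means_cached(float(alpha), int(k)))


def _gamma_category_means_impl(alpha: float, k: int) -> np.ndarray:
    """Mean rate of each of k equal-probability Gamma(alpha, mean 1) slices."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X; X in (a,b)] = P(alpha+1, b*alpha) - P(alpha+1, a*alpha) for mean-1 gamma
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    upper[-1] = 1.0
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    means = k * (upper - lower)
    return means / means.mean() * 1.0


def transition_matrix(model: SubstModel, t: float) -> np.ndarray:
    """4x4 transition probability matrix exp(Q t) for the normalised Q.

    ``t`` is in expected substitutions/site; negative ``t`` is rejected.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    lam, V, Vinv = model.decomposition()
    P = (V * np.exp(lam * t)[None, :]) @ Vinv
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
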