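"""General time-reversible (GTR) nucleotide substitution models.

A GTR model is parameterised by five free exchangeabilities relative to
the G<->T rate, which is fixed at 1, and four base frequencies.  The rate
order is (A<->C, A<->G, A<->T, C<->G, C<->T); bases are ordered A, C, G, T
and a site-pattern state is the base-4 digit A=0, C=1, G=2, T=3.

The rate matrix Q is normalised so that ``-sum_i pi_i Q_ii = 1``: edge
lengths are expected numbers of substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GTRModel", "BASES", "RATE_PAIRS", "build_rate_matrix",
           "transition_matrix"]

BASES = "ACGT"
#: Index pairs of the six exchangeabilities, in rate-vector order
#: (A<->C, A<->G, A<->T, C<->G, C<->T, G<->T); the last is the reference.
RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class GTRModel:
    """GTR model: 5 free exchangeabilities (G<->T = 1) + base frequencies.

    Parameters
    ----------
    rates : 5 floats
        Exchangeabilities (A<->C, A<->G, A<->T, C<->G, C<->T) relative to
        G<->T = 1.  All positive.
    freqs : 4 floats
        Stationary base frequencies (A, C, G, T); positive, summing to 1.
    """

    rates: tuple[float, ...]
    freqs: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        object.__setattr__(self, "freqs", tuple(float(f) for f in self.freqs))
        if len(self.rates) != 5:
            raise ValueError("need 5 exchangeabilities (G<->T is fixed at 1)")
        if len(self.freqs) != 4:
            raise ValueError("need 4 base frequencies")
        if any(r <= 0 for r in self.rates):
            raise ValueError("exchangeabilities must be positive")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("frequencies must be positive")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")

    @classmethod
    def jc(cls) -> "GTRModel":
        """Jukes--Cantor: all exchangeabilities 1, uniform frequencies."""
        return cls((1.0,) * 5, (0.25,) * 4)

    @property
    def rates6(self) -> np.ndarray:
        """All six exchangeabilities, G<->T = 1 appended."""
        return np.array([*self.rates, 1.0])

    def rate_matrix(self) -> np.ndarray:
        """The normalised 4x4 rate matrix Q (see module docstring)."""
        return build_rate_matrix(self)

    def eigen(self):
        """Symmetric eigendecomposition of Q for fast exponentiation.

        Q is similar to the symmetric matrix ``S = D Q D^-1`` with
        ``D = diag(sqrt(pi))`` (time reversibility), so
        ``expm(Q t) = D^-1 V exp(L t) V' D`` with real eigenpairs (V, L).
        Returns ``(left, lam, right)`` with
        ``P(t) = left @ diag(exp(lam t)) @ right``.
        """
        q = self.rate_matrix()
        d = np.sqrt(np.asarray(self.freqs))
        s = q * d[:, None] / d[None, :]
        s = 0.5 * (s + s.T)  # enforce exact symmetry
        lam, v = np.linalg.eigh(s)
        left = v / d[:, None]
        right = v.T * d[None, :]
        return left, lam, right

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths, shape ``t.shape + (4, 4)``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch lengths must be non-negative")
        left, lam, right = self.eigen()
        e = np.exp(t[..., None] * lam)          # (..., 4)
        p = (left * e[..., None, :]) @ right    # (..., 4, 4)
        np.clip(p, 0.0, 1.0, out=p)
        return p


def build_rate_matrix(model: GTRModel) -> np.ndarray:
    """Normalised GTR rate matrix: pi Q = 0, zero row sums, unit mean rate."""
    q = np.zeros((4, 4))
    pi = np.asarray(model.freqs)
    for r, (i, j) in zip(model.rates6, RATE_PAIRS):
        q[i, j] = r * pi[j]
        q[j, i] = r * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ np.diag(q))
    return q / mu


def transition_matrix(model: GTRModel, t: float) -> np.ndarray:
    """The 4x4 substitution probability matrix after branch length ``t``."""
    return model.transition_matrices(np.asarray(float(t)))
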