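"""Substitution models for simulation and likelihood.

Continuous-time reversible Markov models over binary, nucleotide and
amino-acid alphabets.  A model is built from a symmetric exchangeability
matrix ``S`` and equilibrium frequencies ``pi``: ``Q[i,j] = S[i,j]*pi[j]``
with rows summing to zero, scaled so the expected substitution rate at
equilibrium is one — branch lengths are then expected substitutions per
site.  Transition matrices come from the symmetrized eigendecomposition,
so arbitrary ``P(t)`` evaluations are cheap.

Among-site rate heterogeneity uses the discrete gamma approximation with
median category rates renormalized to mean one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from ._aadata import AA_ORDER, LG_FREQS, LG_LOWER_TRIANGLE, WAG_FREQS, WAG_LOWER_TRIANGLE

__all__ = [
    "SubstitutionModel",
    "ModelSpec",
    "discrete_gamma_rates",
    "two_state_model",
    "gtr_model",
    "jukes_cantor_model",
    "lg_model",
    "wag_model",
    "AA_ORDER",
]

NT_ORDER = "ACGT"


class SubstitutionModel:
    """Reversible CTMC over a finite alphabet, normalized to rate 1."""

    def __init__(self, name: str, states: str, exchangeabilities: np.ndarray,
                 freqs: np.ndarray) -> None:
        S = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        k = len(states)
        if S.shape != (k, k) or not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric k x k")
        if pi.shape != (k,) or np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be positive and sum to 1")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        Q /= scale
        self.name = name
        self.states = states
        self.freqs = pi
        self.Q = Q
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        evals, V = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._U = V / sq[:, None]
        self._Uinv = V.T * sq[None, :]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are conditional distributions."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._U * np.exp(self._evals * t)[None, :]) @ self._Uinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Stack of P(t*r) for each rate category, shape (ncat, k, k)."""
        return np.stack([self.transition_matrix(t * r) for r in rates])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SubstitutionModel {self.name} ({self.n_states} states)>"


def discrete_gamma_rates(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Median rates of the K-category discrete gamma, renormalized to mean 1."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    q = (2.0 * np.arange(n_cat) + 1.0) / (2.0 * n_cat)
    r = gamma_dist.ppf(q, a=alpha, scale=1.0 / alpha)
    return r / r.mean()


def _expand_lower_triangle(tri: Sequence[Sequence[float]], k: int) -> np.ndarray:
    S = np.zeros((k, k))
    for i, row in enumerate(tri, start=1):
        for j, x in enumerate(row):
            S[i, j] = S[j, i] = x
    return S


def two_state_model(freqs: Optional[Sequence[float]] = None) -> SubstitutionModel:
    """Two-state (0/1) gain/loss model; uniform frequencies by default."""
    pi = np.array([0.5, 0.5]) if freqs is None else np.asarray(freqs, float)
    S = np.array([[0.0, 1.0], [1.0, 0.0]])
    return SubstitutionModel("BIN", "01", S, pi)


def gtr_model(rates: Optional[Sequence[float]] = None,
              freqs: Optional[Sequence[float]] = None) -> SubstitutionModel:
    """General time-reversible nucleotide model.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT, GT
    (all 1 by default, giving the F81 special case).
    """
    r = np.ones(6) if rates is None else np.asarray(rates, float)
    if r.shape != (6,) or np.any(r <= 0):
        raise ValueError("need six positive exchangeabilities")
    pi = np.full(4, 0.25) if freqs is None else np.asarray(freqs, float)
    S = np.zeros((4, 4))
    S[0, 1] = S[1, 0] = r[0]
    S[0, 2] = S[2, 0] = r[1]
    S[0, 3] = S[3, 0] = r[2]
    S[1, 2] = S[2, 1] = r[3]
    S[1, 3] = S[3, 1] = r[4]
    S[2, 3] = S[3, 2] = r[5]
    return SubstitutionModel("GTR", NT_ORDER, S, pi)


def jukes_cantor_model() -> SubstitutionModel:
    return gtr_model()


def lg_model(freqs: Optional[Sequence[float]] = None) -> SubstitutionModel:
    """LG amino-acid model; model frequencies unless ``freqs`` given (+F)."""
    S = _expand_lower_triangle(LG_LOWER_TRIANGLE, 20)
    pi = np.asarray(LG_FREQS if freqs is None else freqs, float)
    return SubstitutionModel("LG", AA_ORDER, S, pi)


def wag_model(freqs: Optional[Sequence[float]] = None) -> SubstitutionModel:
    S = _expand_lower_triangle(WAG_LOWER_TRIANGLE, 20)
    pi = np.asarray(WAG_FREQS if freqs is None else freqs, float)
    return SubstitutionModel("WAG", AA_ORDER, S, pi)


_FAMILIES = {
    "binary": two_state_model,
    "gtr": gtr_model,
    "lg": lg_model,
    "wag": wag_model,
}


@dataclass
class ModelSpec:
    """A named model family plus rate-heterogeneity settings.

    ``empirical_freqs`` requests "+F" behaviour: equilibrium frequencies are
    counted from the data matrix when the model is resolved.  ``alpha`` is
    the gamma shape; four discrete categories by convention.
    """

    family: str
    alpha: float = 1.0
    n_cat: int = 4
    empirical_freqs: bool = False
    freqs: Optional[np.ndarray] = None
    gtr_rates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unsupported model family {self.family!r}; "
                f"known: {sorted(_FAMILIES)}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def resolve(self, empirical: Optional[np.ndarray] = None) -> SubstitutionModel:
        """Instantiate the substitution model, applying +F if requested."""
        pi = self.freqs
        if self.empirical_freqs:
            if empirical is None:
                raise ValueError("empirical frequencies requested but none supplied")
            pi = empirical
        if self.family == "gtr":
            return gtr_model(self.gtr_rates, pi)
        if self.family == "binary":
            return two_state_model(pi)
        return _FAMILIES[self.family](pi)

    def rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_cat)
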