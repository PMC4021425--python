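"""Reversible nucleotide substitution models (HKY, GTR).

A model is parameterized by stationary frequencies ``pi`` and the six
symmetric exchangeabilities (AC, AG, AT, CG, CT, GT).  The rate matrix is
normalized to one expected substitution per site per unit branch length, and
transition matrices are computed through the symmetric eigendecomposition
available for any reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

NUCLEOTIDES = "ACGT"

__all__ = ["SubstitutionModel", "jc_model", "hky_model", "gtr_model", "NUCLEOTIDES"]


@dataclass
class SubstitutionModel:
    freqs: np.ndarray
    exchangeabilities: np.ndarray  # order: AC, AG, AT, CG, CT, GT

    def __post_init__(self) -> None:
        pi = np.asarray(self.freqs, dtype=float)
        x = np.asarray(self.exchangeabilities, dtype=float)
        if pi.shape != (4,) or x.shape != (6,):
            raise ValueError("expected 4 frequencies and 6 exchangeabilities")
        if np.any(pi <= 0) or np.any(x <= 0):
            raise ValueError("frequencies and exchangeabilities must be positive")
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        self.freqs = pi / pi.sum()
        self.exchangeabilities = x
        self._decompose()

    def _decompose(self) -> None:
        pi = self.freqs
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        S = np.array(
            [
                [0.0, ac, ag, at],
                [ac, 0.0, cg, ct],
                [ag, cg, 0.0, gt],
                [at, ct, gt, 0.0],
            ]
        )
        Q = S * pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()  # expected rate
        Q /= mu
        self.Q = Q
        # symmetric form: B = diag(sqrt(pi)) Q diag(1/sqrt(pi))
        rt = np.sqrt(pi)
        B = rt[:, None] * Q / rt[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._w = w
        self._L = U / rt[None, :].T  # diag(1/sqrt(pi)) U
        self._R = (U * rt[:, None]).T  # U^T diag(sqrt(pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._L * np.exp(self._w * t)[None, :]) @ self._R
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def jc_model() -> SubstitutionModel:
    return SubstitutionModel(np.full(4, 0.25), np.ones(6))


def hky_model(kappa: float = 2.0, freqs: Sequence[float] | None = None) -> SubstitutionModel:
    """HKY: transitions (AG, CT) scaled by kappa relative to transversions."""
    if freqs is None:
        freqs = np.full(4, 0.25)
    ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    return SubstitutionModel(np.asarray(freqs, dtype=float), ex)


def gtr_model(
    exchangeabilities: Sequence[float], freqs: Sequence[float]
) -> SubstitutionModel:
    return SubstitutionModel(np.asarray(freqs, dtype=float),
                             np.asarray(exchangeabilities, dtype=float))
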