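"""Nucleotide substitution models (JC69, K80, HKY85).

The HKY85 rate matrix distinguishes transitions from transversions by the
ratio ``kappa`` and allows arbitrary stationary base frequencies; JC69 and
K80 are its equal-frequency special cases (kappa = 1 for JC69). Rate
matrices are normalized so branch lengths are expected substitutions per
site; transition probabilities P(t) = exp(Qt) come from the symmetric
eigendecomposition available for any reversible Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: fixed state order used throughout
STATES = "ACGT"
STATE_INDEX = {b: i for i, b in enumerate(STATES)}

# transition partners in ACGT order: A<->G, C<->T
_TRANSITION = np.array(
    [
        [0, 0, 1, 0],
        [0, 0, 0, 1],
        [1, 0, 0, 0],
        [0, 1, 0, 0],
    ],
    dtype=bool,
)


@dataclass
class SubstitutionModel:
    """A named substitution model with its free parameters.

    ``base_freqs`` is only meaningful for HKY85; ``None`` means "use the
    empirical frequencies of the data at hand" (resolved by the caller).
    """

    name: str = "HKY85"
    kappa: float = 2.0
    base_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.name not in ("JC69", "K80", "HKY85"):
            raise ValueError(f"unknown model {self.name!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.name == "JC69":
            self.kappa = 1.0
        if self.name in ("JC69", "K80"):
            self.base_freqs = np.full(4, 0.25)
        elif self.base_freqs is not None:
            self.base_freqs = np.asarray(self.base_freqs, dtype=float)
            if self.base_freqs.shape != (4,) or abs(self.base_freqs.sum() - 1) > 1e-8:
                raise ValueError("base_freqs must be a 4-vector summing to 1")

    @property
    def n_free_params(self) -> int:
        """Free parameters estimated from data (empirical freqs count zero)."""
        return 0 if self.name == "JC69" else 1  # kappa

    def resolved(self, freqs: np.ndarray | None = None) -> "SubstitutionModel":
        """Copy with base frequencies fixed (for HKY85 with empirical freqs)."""
        if self.name != "HKY85" or self.base_freqs is not None:
            return self
        if freqs is None:
            raise ValueError("HKY85 needs base frequencies")
        return SubstitutionModel("HKY85", self.kappa, np.asarray(freqs, float))


def rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalized HKY85-family rate matrix Q (rows sum to zero)."""
    pi = model.base_freqs
    if pi is None:
        raise ValueError("model has unresolved base frequencies")
    Q = np.tile(pi, (4, 1)).astype(float)
    Q[_TRANSITION] *= model.kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()  # expected rate
    return Q / mu


class TransitionProbabilities:
    """Cached eigendecomposition of a reversible Q for fast P(t)."""

    def __init__(self, model: SubstitutionModel):
        self.model = model
        self.pi = model.base_freqs
        Q = rate_matrix(model)
        sq = np.sqrt(self.pi)
        B = (Q * sq[:, None]) / sq[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2)
        self.lam = lam
        self.right = U / sq[:, None]  # diag(1/sq) @ U
        self.left = U.T * sq[None, :]  # U.T @ diag(sq)

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """P(t); for an array of m branch lengths returns shape (m, 4, 4)."""
        if np.isscalar(t) or getattr(t, "ndim", 0) == 0:
            P = (self.right * np.exp(float(t) * self.lam)) @ self.left
            np.maximum(P, 0.0, out=P)
            return P
        t = np.asarray(t, dtype=float)
        e = np.exp(np.multiply.outer(t, self.lam))  # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", self.right, e, self.left)
        return np.clip(P, 0.0, 1.0)


def empirical_base_freqs(rows: list[str]) -> np.ndarray:
    """Base frequencies counted over A/C/G/T characters of all rows."""
    counts = np.zeros(4)
    for row in rows:
        up = row.upper()
        for i, b in enumerate(STATES):
            counts[i] += up.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return counts / total
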