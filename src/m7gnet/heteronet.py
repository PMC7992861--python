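"""Heterogeneous site-disease network assembly.

The adjacency matrix stacks the three information sources into one symmetric
block matrix over m sites followed by n diseases::

    A = [[A_SS, A_SD],      W = [[1, W_SD],
         [A_SD^T, A_DD]]         [W_SD^T, 1]]

The companion mask ``W`` marks which entries the factorization loss may look
at: similarity blocks are fully observed (all ones) while the site-disease
block is observed only at known associations.  Unknown associations are
unobserved (A = 0 *and* W = 0), not observed negatives.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractError, ValidationError
from .io import AssociationMatrix
from .similarity import SimilarityMatrix


@dataclass
class HeteroNetwork:
    """Adjacency ``A`` and mask ``W`` over ``m`` sites + ``n`` diseases."""

    m: int
    n: int
    A: np.ndarray = field(repr=False)
    W: np.ndarray = field(repr=False)
    site_labels: list[str] = field(default_factory=list)
    disease_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.m + self.n
        if self.A.shape != (p, p) or self.W.shape != (p, p):
            raise ContractError(
                f"A/W shapes {self.A.shape}/{self.W.shape} do not match m+n={p}"
            )
        self.validate()

    def validate(self) -> "HeteroNetwork":
        for name, M in (("A", self.A), ("W", self.W)):
            if np.abs(M - M.T).max() > 1e-10:
                raise ValidationError(f"{name} is not symmetric")
        if not np.isin(self.W, (0.0, 1.0)).all():
            raise ValidationError("mask entries must be 0 or 1")
        return self

    # --- block views -----------------------------------------------------
    @property
    def a_ss(self) -> np.ndarray:
        return self.A[: self.m, : self.m]

    @property
    def a_sd(self) -> np.ndarray:
        return self.A[: self.m, self.m :]

    @property
    def a_dd(self) -> np.ndarray:
        return self.A[self.m :, self.m :]

    @property
    def w_sd(self) -> np.ndarray:
        return self.W[: self.m, self.m :]

    def copy(self) -> "HeteroNetwork":
        return HeteroNetwork(
            self.m,
            self.n,
            self.A.copy(),
            self.W.copy(),
            list(self.site_labels),
            list(self.disease_labels),
        )

    def mask_out(self, held_out: Sequence[tuple[int, int]]) -> "HeteroNetwork":
        """Return a copy with the given known (site, disease) pairs hidden.

        For each held-out pair the mask is cleared *and* the association value
        is zeroed (at both symmetric positions), so the hidden positives
        cannot leak into the fit through either matrix.
        """
        net = self.copy()
        for i, j in held_out:
            r, c = i, self.m + j
            if not (0 <= i < self.m and 0 <= j < self.n):
                raise ContractError(f"pair ({i}, {j}) out of range")
            if net.W[r, c] != 1.0 or net.A[r, c] != 1.0:
                raise ContractError(
                    f"pair ({i}, {j}) is not a known association; cannot hold out"
                )
            net.A[r, c] = net.A[c, r] = 0.0
            net.W[r, c] = net.W[c, r] = 0.0
        return net.validate()


def assemble(
    a_ss: SimilarityMatrix,
    a_sd: AssociationMatrix,
    a_dd: SimilarityMatrix,
) -> HeteroNetwork:
    """Assemble the heterogeneous adjacency and mask from the three blocks."""
    if list(a_ss.labels) != list(a_sd.sites):
        raise ContractError("site similarity labels do not match association rows")
    if list(a_dd.labels) != list(a_sd.diseases):
        raise ContractError("disease similarity labels do not match association columns")
    m, n = len(a_sd.sites), len(a_sd.diseases)
    p = m + n
    A = np.zeros((p, p))
    A[:m, :m] = a_ss.values
    A[m:, m:] = a_dd.values
    A[:m, m:] = a_sd.values
    A[m:, :m] = a_sd.values.T
    W = np.ones((p, p))
    W[:m, m:] = (a_sd.values == 1.0).astype(float)
    W[m:, :m] = W[:m, m:].T
    return HeteroNetwork(m, n, A, W, list(a_sd.sites), list(a_sd.diseases))
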