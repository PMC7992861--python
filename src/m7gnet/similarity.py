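"""Pairwise similarity networks over sites and diseases.

Site similarities come in two flavours: Jaccard over binary chemical feature
vectors and cosine over CNF vectors.  The two are fused by a convex
combination weighted by ``alpha`` (alpha = 0 gives the chemical network,
alpha = 1 the CNF network).  Disease semantic similarity is an input computed
externally (e.g. by a DAG-based Wang-style measure) and is only validated
here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

_SYMMETRY_TOL = 1e-10


@dataclass
class SimilarityMatrix:
    """Square, symmetric, [0, 1]-valued similarity matrix with unit diagonal."""

    labels: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "integrated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> "SimilarityMatrix":
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise ValidationError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{p} labels"
            )
        if len(set(self.labels)) != p:
            raise ValidationError("similarity labels must be unique")
        if p == 0:
            return self
        gap = float(np.abs(self.values - self.values.T).max())
        if gap > _SYMMETRY_TOL:
            raise ValidationError(f"asymmetry {gap:.3g} exceeds {_SYMMETRY_TOL:.0e}")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(f"entries outside [0, 1]: min={lo:.6g}, max={hi:.6g}")
        if not np.allclose(np.diag(self.values), 1.0):
            bad = [self.labels[i] for i in np.flatnonzero(~np.isclose(np.diag(self.values), 1.0))]
            raise ValidationError(f"diagonal entries differ from 1 for {bad[:5]}")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "integrated") -> "SimilarityMatrix":
        return cls([str(x) for x in frame.index], frame.to_numpy(dtype=float), kind)


def jaccard_binary(u, v) -> float:
    """Jaccard coefficient of two equal-length binary vectors.

    Positions where both vectors carry a 1 form the intersection; positions
    where at least one does form the union.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1:
        raise ContractError(f"shape mismatch: {u.shape} vs {v.shape}")
    if not (np.isin(u, (0, 1)).all() and np.isin(v, (0, 1)).all()):
        raise ContractError("jaccard_binary requires {0,1}-valued vectors")
    union = np.count_nonzero((u + v) > 0)
    if union == 0:
        raise ContractError("Jaccard similarity undefined for two all-zero vectors")
    inter = np.count_nonzero((u > 0) & (v > 0))
    return inter / union


def cosine(u, v) -> float:
    """Cosine similarity u.v / (||u|| ||v||) of two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ContractError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ContractError("cosine similarity undefined for a zero-norm vector")
    return float(u @ v) / (nu * nv)


def similarity_matrix(features: pd.DataFrame, metric: str) -> SimilarityMatrix:
    """All-pairs similarity of the feature rows under the given metric.

    ``metric`` is ``"jaccard"`` (binary features) or ``"cosine"``.  The result
    is symmetric by construction with the diagonal forced to exactly 1; at
    ~10^3 sites the dense computation is trivially affordable, so no
    sparsification is applied.
    """
    if features.shape[0] < 1:
        raise ContractError("need at least one feature row")
    X = features.to_numpy(dtype=float)
    if metric == "jaccard":
        if not np.isin(X, (0.0, 1.0)).all():
            raise ContractError("jaccard metric requires binary features")
        inter = X @ X.T
        rowsum = X.sum(axis=1)
        union = rowsum[:, None] + rowsum[None, :] - inter
        if (union == 0).any():
            raise ContractError("all-zero feature rows have undefined Jaccard similarity")
        values = inter / union
        kind = "chemical"
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            raise ContractError("zero-norm feature rows have undefined cosine similarity")
        Xn = X / norms[:, None]
        values = Xn @ Xn.T
        kind = "cnf"
    else:
        raise ContractError(f"unknown metric {metric!r}")
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix([str(i) for i in features.index], values, kind)


def integrate(csn: SimilarityMatrix, cnfsn: SimilarityMatrix, alpha: float) -> SimilarityMatrix:
    """Convex combination (1 - alpha) * chemical + alpha * CNF similarity."""
    if csn.labels != cnfsn.labels:
        raise ContractError("similarity networks have mismatched labels")
    if not 0.0 <= alpha <= 1.0:
        raise ContractError(f"alpha={alpha} outside [0, 1]")
    values = (1.0 - alpha) * csn.values + alpha * cnfsn.values
    return SimilarityMatrix(list(csn.labels), values, "integrated")


def validate_disease_similarity(
    matrix: pd.DataFrame | SimilarityMatrix, tol: float = 1e-8
) -> SimilarityMatrix:
    """Validate an externally computed disease semantic similarity matrix.

    Checks squareness, symmetry within ``tol`` (then symmetrizes exactly),
    [0, 1] range and unit diagonal, listing offending labels on failure.
    """
    if isinstance(matrix, SimilarityMatrix):
        frame = matrix.to_frame()
    else:
        frame = matrix
    if frame.shape[0] != frame.shape[1]:
        raise ValidationError(f"disease similarity not square: {frame.shape}")
    values = frame.to_numpy(dtype=float)
    labels = [str(x) for x in frame.index]
    if values.size:
        gap = float(np.abs(values - values.T).max())
        if gap > tol:
            raise ValidationError(f"asymmetry {gap:.3g} exceeds tolerance {tol:.3g}")
        values = (values + values.T) / 2.0
        out_of_range = np.argwhere((values < 0.0) | (values > 1.0))
        if out_of_range.size:
            bad = sorted({labels[i] for i, _ in out_of_range[:10]})
            raise ValidationError(f"entries outside [0, 1] involving {bad}")
        off_diag = np.flatnonzero(~np.isclose(np.diag(values), 1.0, atol=tol))
        if off_diag.size:
            raise ValidationError(
                f"diagonal differs from 1 for {[labels[i] for i in off_diag[:10]]}"
            )
        np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels, values, "disease")
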