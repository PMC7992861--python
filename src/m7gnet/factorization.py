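"""Masked ridge-regularized low-rank factorization solved by ALS.

The heterogeneous adjacency ``A`` is approximated as ``U V^T`` with
``U, V in R^{(m+n) x k}`` by minimizing the masked loss

    L = || W o (A - U V^T) ||_F^2 + lambda1 ||U||_F^2 + lambda2 ||V||_F^2

where ``o`` is the Hadamard product: only entries with mask 1 contribute to
the reconstruction term.  Alternating least squares solves, in closed form,
one ridge system per row of U (with V fixed) and vice versa, which makes the
loss non-increasing across full sweeps; the problem is non-convex, so the
fixed point reached is a local minimum depending on the (seeded) random
initialization.

The solver exploits the block structure of the mask: a site row observes all
m site columns plus its known diseases, so its normal-equation Gram matrix is
the precomputed site-block Gram plus a small per-row correction (and
symmetrically for disease rows).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ContractError
from .heteronet import HeteroNetwork

logger = logging.getLogger(__name__)


@dataclass
class MFConfig:
    """Hyperparameters of the masked factorization.

    ``k`` is the latent rank (number of independent factors assumed to govern
    the association pattern), ``lambda1``/``lambda2`` the ridge penalties on
    U and V, ``tol`` the relative loss-change stopping threshold.
    """

    k: int = 90
    lambda1: float = 0.25
    lambda2: float = 0.25
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ContractError(f"k={self.k} must be a positive integer")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ContractError("lambda1 and lambda2 must be strictly positive")
        if self.tol <= 0:
            raise ContractError("tol must be strictly positive")
        if self.max_iter < 1:
            raise ContractError("max_iter must be a positive integer")


@dataclass
class FactorPair:
    """Fitted factor matrices with per-sweep loss diagnostics."""

    U: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)
    loss_trace: list[float]
    n_iter: int
    converged: bool


@dataclass
class ScoreMatrix:
    """Predicted site-disease association scores with labels."""

    site_labels: list[str]
    disease_labels: list[str]
    values: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_labels, columns=self.disease_labels)


def masked_loss(
    net: HeteroNetwork,
    U: np.ndarray,
    V: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> float:
    """Value of the regularized masked reconstruction loss."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (np.isfinite(U).all() and np.isfinite(V).all()):
        raise ContractError("non-finite factor entries")
    R = net.W * (net.A - U @ V.T)
    return float(
        np.sum(R * R) + lambda1 * np.sum(U * U) + lambda2 * np.sum(V * V)
    )


def _as_generator(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


class MaskedALS(BaseEstimator):
    """Masked low-rank matrix factorization fitted by alternating least squares.

    Parameters
    ----------
    k : int
        Latent rank of the factorization.
    lambda1, lambda2 : float
        Ridge penalties on U and V; must be strictly positive (they also keep
        every row-wise normal system non-singular).
    max_iter : int
        Maximum number of full ALS sweeps.
    tol : float
        Stop when the relative loss change between sweeps falls below this.
    random_state : int, Generator or None
        Seeds the i.i.d. normal initialization (scale 1/sqrt(k), which keeps
        initial reconstructions O(1)).

    Attributes
    ----------
    U_, V_ : ndarray of shape (m+n, k)
        Fitted factor matrices.
    loss_trace_ : list of float
        Loss after every full sweep (non-increasing).
    n_iter_ : int
        Number of sweeps performed.
    converged_ : bool
        Whether the relative-change criterion was met within ``max_iter``.
    """

    def __init__(self, k=90, lambda1=0.25, lambda2=0.25, max_iter=200, tol=1e-6, random_state=None):
        self.k = k
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _validate(self, net: HeteroNetwork) -> None:
        MFConfig(self.k, self.lambda1, self.lambda2, self.max_iter, self.tol)
        if self.k >= net.m + net.n:
            raise ContractError(f"k={self.k} must be < m+n={net.m + net.n}")

    def fit(self, X: HeteroNetwork, y=None) -> "MaskedALS":
        """Fit U, V on a heterogeneous network (ignores ``y``)."""
        net = X
        self._validate(net)
        m, n = net.m, net.n
        p = m + n
        rng = _as_generator(self.random_state)
        scale = 1.0 / np.sqrt(self.k)
        U = rng.normal(scale=scale, size=(p, self.k))
        V = rng.normal(scale=scale, size=(p, self.k))

        # Known-association index lists drive the per-row Gram corrections.
        w_sd = net.w_sd
        site_known = [np.flatnonzero(w_sd[r] == 1.0) for r in range(m)]
        disease_known = [np.flatnonzero(w_sd[:, j] == 1.0) for j in range(n)]

        trace: list[float] = []
        converged = False
        sweep = 0
        for sweep in range(1, self.max_iter + 1):
            U = _update_rows(net.A, m, site_known, disease_known, V, self.lambda1)
            V = _update_rows(net.A, m, site_known, disease_known, U, self.lambda2)
            loss = masked_loss(net, U, V, self.lambda1, self.lambda2)
            if trace and abs(trace[-1] - loss) <= self.tol * max(trace[-1], 1e-300):
                trace.append(loss)
                converged = True
                break
            trace.append(loss)
        if not converged:
            logger.warning(
                "ALS did not converge in %d sweeps (last relative change %.3g)",
                self.max_iter,
                abs(trace[-2] - trace[-1]) / max(trace[-2], 1e-300) if len(trace) > 1 else float("nan"),
            )
        self.U_, self.V_ = U, V
        self.loss_trace_ = trace
        self.n_iter_ = sweep
        self.converged_ = converged
        self.m_, self.n_ = m, n
        self.site_labels_ = list(net.site_labels)
        self.disease_labels_ = list(net.disease_labels)
        return self

    def reconstruct(self) -> np.ndarray:
        """Full (m+n) x (m+n) reconstruction U V^T."""
        return self.U_ @ self.V_.T

    def predict(self, X=None) -> np.ndarray:
        """Site-disease score block of the reconstruction.

        The reconstruction is not exactly symmetric, so the two site-disease
        blocks are averaged.  ``X`` is accepted for interface compatibility
        and ignored: scores are for the network the model was fitted on.
        """
        R = self.reconstruct()
        m = self.m_
        return (R[:m, m:] + R[m:, :m].T) / 2.0


def _update_rows(A, m, site_known, disease_known, F, lam):
    """Solve the ridge system for every row of one factor, the other (F) fixed.

    Row r's observed column set is its own similarity block plus its known
    cross-block entries, so the Gram matrix is a shared base plus a small
    per-row correction.
    """
    p, k = F.shape
    n = p - m
    Fs, Fd = F[:m], F[m:]
    eye = lam * np.eye(k)
    base_s = Fs.T @ Fs + eye
    base_d = Fd.T @ Fd + eye
    out = np.empty_like(F)
    Bs = A[:m, :m] @ Fs  # similarity-block part of each site row's rhs
    Bd = A[m:, m:] @ Fd
    for r in range(m):
        cols = site_known[r]
        if cols.size:
            Fe = Fd[cols]
            M = base_s + Fe.T @ Fe
            b = Bs[r] + A[r, m + cols] @ Fe
        else:
            M, b = base_s, Bs[r]
        out[r] = np.linalg.solve(M, b)
    for j in range(n):
        rows = disease_known[j]
        if rows.size:
            Fe = Fs[rows]
            M = base_d + Fe.T @ Fe
            b = Bd[j] + A[m + j, rows] @ Fe
        else:
            M, b = base_d, Bd[j]
        out[m + j] = np.linalg.solve(M, b)
    return out


def fit_als(net: HeteroNetwork, config: MFConfig) -> FactorPair:
    """Functional wrapper over :class:`MaskedALS` returning a :class:`FactorPair`."""
    est = MaskedALS(
        k=config.k,
        lambda1=config.lambda1,
        lambda2=config.lambda2,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
    ).fit(net)
    return FactorPair(est.U_, est.V_, est.loss_trace_, est.n_iter_, est.converged_)


def predict_scores(net: HeteroNetwork, factors: FactorPair) -> ScoreMatrix:
    """Average the two symmetric site-disease blocks of the reconstruction."""
    m, n = net.m, net.n
    if factors.U.shape[0] != m + n or factors.V.shape[0] != m + n:
        raise ContractError(
            f"factor rows {factors.U.shape[0]} do not match network size {m + n}"
        )
    R = factors.U @ factors.V.T
    values = (R[:m, m:] + R[m:, :m].T) / 2.0
    return ScoreMatrix(list(net.site_labels), list(net.disease_labels), values)
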