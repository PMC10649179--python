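"""Distributed-source inverse solutions: WMNE and LORETA.

The scalp potential is linear in the source amplitudes, u = K J, with
many more sources than electrodes, so the inverse is regularised.  WMNE
returns the minimum ||W J|| solution; LORETA additionally penalises the
graph Laplacian of the source distribution (adjacent cortical patches
are strongly synchronous), with Tikhonov regularisation weight lambda.
The reference electrode is unknown, so all operators act through the
average-reference projector H, which annihilates any constant offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .headmodel import LeadField, SourceSpace

logger = logging.getLogger(__name__)


def average_reference_operator(n: int) -> np.ndarray:
    """H = I - (1/n) 1 1^T : symmetric, idempotent, kills constants."""
    if n < 2:
        raise ValueError("need at least 2 electrodes")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def column_norm_weights(K: np.ndarray) -> np.ndarray:
    """Depth-weighting diagonal W: Euclidean norm of each gain column.

    Deep sources have weak gain columns; weighting by the column norm
    counteracts the bias of the plain minimum-norm solution toward
    superficial sources.  Returns the 1-D diagonal of W.
    """
    K = np.asarray(K, float)
    w = np.linalg.norm(K, axis=0)
    bad = np.where(w == 0)[0]
    if len(bad):
        raise ValueError(f"all-zero lead-field column(s) at source "
                         f"index {bad.tolist()}: degenerate source")
    return w


def source_graph_laplacian(source_space: SourceSpace | np.ndarray,
                           n_vertices: int | None = None) -> np.ndarray:
    """Combinatorial graph Laplacian L = D - A of the source mesh.

    Accepts a :class:`SourceSpace` or an (n_e, 2) edge array.  Symmetric
    positive semi-definite with zero row sums.  A disconnected graph is
    allowed but logged (the smoothness prior then acts per component).
    """
    if isinstance(source_space, SourceSpace):
        edges = source_space.edges()
        n = source_space.n_sources
    else:
        edges = np.asarray(source_space, int)
        n = int(n_vertices if n_vertices is not None else edges.max() + 1)
    A = sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n))
    A = A + A.T
    n_comp, _ = connected_components(A, directed=False)
    if n_comp > 1:
        logger.warning("source graph has %d connected components", n_comp)
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sparse.diags(deg) - A
    return L.toarray()


@dataclass
class InverseModel:
    """Precomputed operators for WMNE/LORETA on one lead field.

    G = H K is the average-referenced gain; W the depth weighting
    (1-D diagonal); L the source-graph Laplacian; ``lam`` the Tikhonov
    weight (0 disables regularisation).
    """

    K: np.ndarray
    W: np.ndarray
    L: np.ndarray
    lam: float = 0.0
    ridge: float = 1e-4
    H: np.ndarray = field(init=False)
    G: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, float)
        self.W = np.asarray(self.W, float).ravel()
        self.L = np.asarray(self.L, float)
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        n, m = self.K.shape
        if self.W.shape != (m,):
            raise ValueError("W must have one entry per source")
        if self.L.shape != (m, m):
            raise ValueError("L must be square over the sources")
        self.H = average_reference_operator(n)
        self.G = self.H @ self.K

    @classmethod
    def from_lead_field(cls, lf: LeadField, lam: float = 0.0,
                        depth_weighting: bool = True,
                        laplacian: bool = True) -> "InverseModel":
        m = lf.K.shape[1]
        W = column_norm_weights(lf.K) if depth_weighting else np.ones(m)
        L = source_graph_laplacian(lf.source_space) if laplacian else np.eye(m)
        return cls(K=lf.K, W=W, L=L, lam=lam)


def _pinv(mat: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Moore-Penrose pseudo-inverse via truncated SVD."""
    return np.linalg.pinv(mat, rcond=rtol)


def solve_wmne(inv: InverseModel, u: np.ndarray) -> np.ndarray:
    """Weighted minimum-norm estimate J = C^-1 G^T (G C^-1 G^T)^+ H u.

    C = W W^T (diagonal); the Gram matrix is rank deficient (average
    reference removes one dimension), hence the pseudo-inverse.  ``u``
    may be a vector or an (n_electrodes, n_times) matrix.
    """
    u = np.asarray(u, float)
    if u.shape[0] != inv.G.shape[0]:
        raise ValueError(f"u has {u.shape[0]} rows, expected "
                         f"{inv.G.shape[0]} electrodes")
    Ci_Gt = inv.G.T / (inv.W**2)[:, None]          # C^-1 G^T
    gram = inv.G @ Ci_Gt
    return Ci_Gt @ (_pinv(gram) @ (inv.H @ u))


def loreta_operator(inv: InverseModel) -> np.ndarray:
    """The linear LORETA inverse operator T with J = T u.

    T = (W L^T L W)^-1 G^T (G (W L^T L W)^-1 G^T + lam H)^+ applied
    after average referencing.  W L^T L W annihilates vectors mapped to
    constants by W^-1 and is stabilised by a small ridge before
    inversion.
    """
    Wd = inv.W
    WLtLW = (Wd[:, None] * (inv.L.T @ inv.L)) * Wd[None, :]
    m = len(Wd)
    # the ridge keeps the constant near-null mode of L from leaking into
    # the estimate; 1e-4 x the mean diagonal scale is small against the
    # informative spectrum but large against the null mode
    WLtLW[np.diag_indices(m)] += inv.ridge * np.trace(WLtLW) / m
    B = np.linalg.solve(WLtLW, inv.G.T)            # (WL^TLW)^-1 G^T
    inner = inv.G @ B + inv.lam * inv.H
    return B @ (_pinv(inner) @ inv.H)


def solve_loreta(inv: InverseModel, u: np.ndarray) -> np.ndarray:
    """LORETA estimate of the source amplitudes for potentials ``u``.

    At lam = 0 with L = I and W = I this reduces to the (unweighted)
    minimum-norm solution of :func:`solve_wmne`.
    """
    u = np.asarray(u, float)
    if u.shape[0] != inv.G.shape[0]:
        raise ValueError(f"u has {u.shape[0]} rows, expected "
                         f"{inv.G.shape[0]} electrodes")
    return loreta_operator(inv) @ u


def choose_lambda(inv: InverseModel, u: np.ndarray,
                  grid: np.ndarray | None = None) -> float:
    """Pick the Tikhonov weight by generalized cross-validation.

    GCV(lam) = n ||(I - A(lam)) H u||^2 / tr(I - A(lam))^2 where
    A(lam) is the influence matrix G T(lam).  ``grid`` holds relative
    weights (default 10 log-spaced values in [1e-6, 1]); each is scaled
    by the mean eigenvalue of the unregularised Gram matrix so the grid
    is commensurate with the data units.  Returns the absolute lambda;
    deterministic, ties go to the smaller value.  ``u`` may be a
    vector or an (n_electrodes, n_times) matrix (pooled residuals).
    """
    u = np.asarray(u, float)
    if grid is None:
        grid = np.logspace(-6, 0, 10)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("lambda values must be non-negative")
    Hu = inv.H @ u
    n = inv.G.shape[0]
    base = InverseModel(K=inv.K, W=inv.W, L=inv.L, lam=0.0, ridge=inv.ridge)
    # Gram matrix G (W L^T L W + ridge)^-1 G^T and its mean eigenvalue
    Wd = base.W
    A0 = (Wd[:, None] * (base.L.T @ base.L)) * Wd[None, :]
    A0[np.diag_indices(len(Wd))] += base.ridge * np.trace(A0) / len(Wd)
    gram = base.G @ np.linalg.solve(A0, base.G.T)
    scale = np.trace(gram) / (n - 1)
    best_lam, best_score = None, np.inf
    for rel in np.sort(grid):
        lam = float(rel * scale)
        A = gram @ _pinv(gram + lam * base.H) @ base.H
        resid = Hu - A @ Hu
        denom = n - np.trace(A)
        score = float(np.sum(resid**2)) * n / max(denom, 1e-12) ** 2
        if score < best_score * (1 - 1e-12):
            best_score, best_lam = score, lam
    return best_lam
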