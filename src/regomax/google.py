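"""Google matrix construction, PageRank/CheiRank and the rank-plane density.

The Google matrix of a directed network is ``G = alpha * S + (1 - alpha)/N``
where ``S`` is the column-stochastic transition matrix of the (binary)
adjacency, dangling columns are replaced by the uniform column ``1/N``, and
``alpha`` is the damping factor (0.85 by default).  ``G`` is never densified:
it is applied matrix-free as ``G v = alpha * S_sparse v + 1 (c . v)`` with the
teleportation-plus-dangling vector ``c`` handled analytically.

The PageRank vector is the right eigenvector ``G P = P``; the CheiRank vector
is the PageRank of the link-inverted network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network import SignedDirectedNetwork

__all__ = [
    "StochasticModel",
    "RankResult",
    "DensityGrid",
    "build_google_matrix",
    "compute_pagerank",
    "rank_plane_density",
]


@dataclass
class StochasticModel:
    """Column-stochastic model ``G = alpha * S + (1 - alpha)/N * ones``.

    ``S`` is stored sparse with dangling columns left all-zero; the uniform
    dangling column ``1/N`` and the rank-1 teleportation term are folded into
    the vector ``c`` so that ``G = alpha * S + 1 c^T`` exactly, with
    ``c_j = (alpha * [j dangling] + 1 - alpha) / N``.
    """

    N: int
    alpha: float
    S: sp.csc_matrix                   # normalized, dangling columns zero
    dangling_set: np.ndarray           # bool mask of zero-out-degree columns
    inverted: bool = False
    weighted: bool = False

    @classmethod
    def from_adjacency(
        cls, A: sp.spmatrix, alpha: float, inverted: bool = False, weighted: bool = False
    ) -> "StochasticModel":
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        A = sp.csc_matrix(A, dtype=float)
        n = A.shape[0]
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        col_sums = np.asarray(A.sum(axis=0)).ravel()
        dangling = col_sums == 0
        inv = np.ones(n)
        inv[~dangling] = 1.0 / col_sums[~dangling]
        S = A @ sp.diags(inv)
        S = sp.csc_matrix(S)
        return cls(N=n, alpha=alpha, S=S, dangling_set=dangling,
                   inverted=inverted, weighted=weighted)

    @property
    def c(self) -> np.ndarray:
        """Per-column rank-1 weight: teleportation plus dangling correction."""
        return (self.alpha * self.dangling_set + (1.0 - self.alpha)) / self.N

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Matrix-free ``G @ v`` (also works columnwise on 2-D arrays)."""
        tail = self.c @ v
        return self.alpha * (self.S @ v) + tail


def build_google_matrix(
    network: SignedDirectedNetwork, alpha: float = 0.85, inverted: bool = False
) -> StochasticModel:
    """Google matrix of the simple (binary, unsigned) network.

    ``inverted=True`` flips every edge direction before normalization — the
    CheiRank construction ``G*`` (its dangling set generally differs from the
    normal one).
    """
    if network.N < 2:
        raise ValueError("network must have at least 2 nodes")
    A = network.adjacency(inverted=inverted)
    return StochasticModel.from_adjacency(A, alpha, inverted=inverted)


@dataclass
class RankResult:
    """PageRank (or CheiRank) probabilities with their 1-based rank index."""

    P: np.ndarray
    K: np.ndarray            # 1-based rank per node: K[j] = rank of node j
    is_cheirank: bool = False
    n_iter: int = 0
    residual: float = 0.0
    order: np.ndarray = field(default=None)  # node indices sorted by rank

    def __post_init__(self):
        if self.order is None:
            self.order = np.argsort(self.K)


def _rank_index(P: np.ndarray) -> np.ndarray:
    """1-based descending-probability ranks, ties broken by ascending index."""
    order = np.lexsort((np.arange(len(P)), -P))
    K = np.empty(len(P), dtype=np.int64)
    K[order] = np.arange(1, len(P) + 1)
    return K


def compute_pagerank(
    model: StochasticModel, tol: float = 1e-14, max_iter: int = 100_000
) -> RankResult:
    """Power iteration ``v <- G v`` from the uniform vector to L1 change < tol."""
    v = np.full(model.N, 1.0 / model.N)
    for it in range(1, max_iter + 1):
        w = model.apply(v)
        w /= w.sum()  # guard against drift; G conserves the sum analytically
        res = float(np.abs(w - v).sum())
        v = w
        if res < tol:
            return RankResult(P=v, K=_rank_index(v), is_cheirank=model.inverted,
                              n_iter=it, residual=res)
    raise RuntimeError(
        f"PageRank power iteration did not reach tol={tol} in {max_iter} "
        f"iterations (final residual {res:.3e})"
    )


@dataclass
class DensityGrid:
    """Node density on the (ln K, ln K*) plane over logarithmic bins.

    Each cell counts the nodes whose rank pair falls inside it, divided by the
    cell capacity — the number of integer ``(K, K*)`` pairs whose logarithms
    fall inside — and the grid is renormalized to total 1.
    """

    grid: np.ndarray
    edges: np.ndarray        # bin edges in ln K, shared by both axes


def _log_bin(K: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin indices of ln K into half-open cells (last cell closed)."""
    idx = np.searchsorted(edges, np.log(K), side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def rank_plane_density(K: np.ndarray, K_star: np.ndarray, bins: int = 100) -> DensityGrid:
    """Density grid of (ln K, ln K*) with capacity-normalized cells."""
    K = np.asarray(K)
    K_star = np.asarray(K_star)
    if K.shape != K_star.shape:
        raise ValueError("K and K* must have the same length")
    n = len(K)
    if n < 2:
        raise ValueError("density grid needs at least 2 nodes (log range empty)")
    edges = np.linspace(0.0, np.log(n), bins + 1)
    # capacity per 1-D bin: number of integers K in [exp(e_m), exp(e_{m+1}))
    all_idx = _log_bin(np.arange(1, n + 1), edges)
    cap1d = np.bincount(all_idx, minlength=bins).astype(float)
    counts = np.zeros((bins, bins))
    np.add.at(counts, (_log_bin(K, edges), _log_bin(K_star, edges)), 1.0)
    capacity = np.outer(cap1d, cap1d)
    grid = np.zeros_like(counts)
    nonzero = capacity > 0
    grid[nonzero] = counts[nonzero] / capacity[nonzero]
    total = grid.sum()
    if total > 0:
        grid /= total
    return DensityGrid(grid=grid, edges=edges)
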