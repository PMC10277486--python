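"""Local spectral (Vicus) matrix construction.

The Vicus matrix is a local alternative to the graph Laplacian. For each
node ``i`` a subnetwork over its K nearest neighbours plus ``i`` itself is
extracted, a label-diffusion fixed point is computed on that subnetwork, and
the diffusion weights are turned into a sparse reconstruction matrix ``B``
expressing each node as a convex combination of its neighbours. The
regularizer is then::

    vir = (I - B)^T (I - B)

which, like the Laplacian, is symmetric positive semidefinite with the
all-ones vector in its null space, but is built from local diffusion rather
than global degrees.

Per node the diffusion weights are the row of ``(1 - alpha) (I - alpha S)^-1``
belonging to the node itself, where ``S`` is the row-stochastic transition
matrix of the subnetwork and ``alpha`` in (0, 1) the diffusion constant.
Node ``i`` occupies the last position of its subnetwork so that the final
element of the weight vector is the self-weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import SimilarityNetwork

__all__ = [
    "DiffusionConfig",
    "VicusMatrix",
    "knn_subnetwork",
    "transition_matrix",
    "diffusion_row",
    "build_B",
    "vicus_matrix",
    "knn_laplacian",
]

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12


@dataclass
class DiffusionConfig:
    """Neighbourhood size and diffusion constant for Vicus construction.

    ``K = 15`` nearest neighbours and diffusion constant ``alpha_diff = 0.9``
    are the reference settings; ``K`` is shrunk per node when fewer
    positive-similarity neighbours exist.
    """

    K: int = 15
    alpha_diff: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_diff < 1.0:
            raise ValueError("alpha_diff must lie in (0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class VicusMatrix:
    """Reconstruction weights ``B`` and local spectral matrix ``vir``."""

    node_ids: list[str]
    B: np.ndarray
    vir: np.ndarray

    def to_tsv(self, vir_path: str | Path,
               b_path: str | Path | None = None) -> None:
        pd.DataFrame(self.vir, index=self.node_ids,
                     columns=self.node_ids).to_csv(
            vir_path, sep="\t", float_format="%.12g")
        if b_path is not None:
            rows, cols = np.nonzero(self.B)
            pd.DataFrame({"i": rows, "j": cols,
                          "value": self.B[rows, cols]}).to_csv(
                b_path, sep="\t", index=False, float_format="%.12g")


def knn_subnetwork(W: SimilarityNetwork, i: int, K: int,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Extract node ``i``'s K-nearest-neighbour subnetwork.

    Returns the neighbour indices (descending similarity, ties broken by
    ascending index) and the similarity submatrix over neighbours plus
    ``i``, with ``i`` in the last position. When fewer than ``K``
    positive-similarity neighbours exist, the neighbourhood shrinks to
    those (minimum one neighbour).
    """
    n = W.n_nodes
    if not 0 <= i < n:
        raise IndexError(f"node index {i} out of range for {n} nodes")
    sims = W.matrix[i].copy()
    candidates = np.array([j for j in range(n) if j != i])
    order = np.lexsort((candidates, -sims[candidates]))
    ranked = candidates[order]
    positive = int(np.sum(sims[candidates] > 0))
    k_eff = min(K, max(positive, 1))
    if positive < K:
        logger.debug("node %d has %d positive-similarity neighbours; "
                     "shrinking K from %d to %d", i, positive, K, k_eff)
    nbrs = ranked[:k_eff]
    ver = np.concatenate([nbrs, [i]])
    return nbrs, W.matrix[np.ix_(ver, ver)]


def transition_matrix(Wi: np.ndarray) -> np.ndarray:
    """Row-normalize a nonnegative subnetwork matrix to row sums of 1.

    Zero rows receive a unit self-loop first (an isolated node diffuses
    only to itself).
    """
    Wi = np.asarray(Wi, dtype=float)
    if Wi.ndim != 2 or Wi.shape[0] != Wi.shape[1]:
        raise ValueError("subnetwork matrix must be square")
    if np.any(Wi < 0):
        raise ValueError("subnetwork matrix must be nonnegative")
    Wi = Wi.copy()
    sums = Wi.sum(axis=1)
    zero_rows = np.nonzero(sums == 0)[0]
    if zero_rows.size:
        logger.debug("adding self-loops to %d all-zero subnetwork rows",
                     zero_rows.size)
        Wi[zero_rows, zero_rows] = 1.0
        sums = Wi.sum(axis=1)
    return Wi / sums[:, None]


def diffusion_row(Si: np.ndarray, alpha_diff: float) -> np.ndarray:
    """Last row of ``(1 - alpha) (I - alpha S)^-1``.

    This is the converged label-diffusion weight vector of the node placed
    last in its subnetwork; entries are nonnegative and sum to one because
    ``S`` is row stochastic and ``alpha < 1``.
    """
    Si = np.asarray(Si, dtype=float)
    k1 = Si.shape[0]
    system = np.eye(k1) - alpha_diff * Si
    try:
        # beta = (1-a) * e_last^T (I - a S)^{-1}  -> solve the transposed system
        beta = (1.0 - alpha_diff) * scipy.linalg.solve(system.T,
                                                       np.eye(k1)[:, -1])
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded by alpha<1
        cond = np.linalg.cond(system)
        raise np.linalg.LinAlgError(
            f"diffusion system singular (condition number {cond:.3g})") from exc
    return beta


def build_B(W: SimilarityNetwork,
            cfg: DiffusionConfig | None = None) -> VicusMatrix:
    """Assemble the sparse reconstruction-weight matrix ``B`` row by row.

    Row ``i`` carries ``beta[:K] / (1 - beta[K])`` on node ``i``'s
    neighbours, where ``beta`` is the diffusion weight vector of the
    subnetwork with ``i`` last; every row sums to one. If the self-weight
    ``beta[K]`` reaches 1 (node isolated from its neighbourhood) the row
    falls back to a uniform distribution over the neighbours.
    """
    cfg = cfg or DiffusionConfig()
    n = W.n_nodes
    if n < 2:
        raise ValueError("need at least two nodes to build a Vicus matrix")
    K = min(cfg.K, n - 1)
    B = np.zeros((n, n))
    for i in range(n):
        nbrs, Wi = knn_subnetwork(W, i, K)
        Si = transition_matrix(Wi)
        beta = diffusion_row(Si, cfg.alpha_diff)
        denom = 1.0 - beta[-1]
        if denom < _DEGENERATE_TOL:
            logger.debug("node %d: degenerate self-weight, uniform fallback", i)
            B[i, nbrs] = 1.0 / len(nbrs)
        else:
            B[i, nbrs] = beta[:-1] / denom
    return VicusMatrix(list(W.node_ids), B, np.zeros((0, 0)))


def vicus_matrix(W: SimilarityNetwork,
                 cfg: DiffusionConfig | None = None) -> VicusMatrix:
    """Build ``vir = (I - B)^T (I - B)`` for a similarity network."""
    vm = build_B(W, cfg)
    I_minus_B = np.eye(len(vm.node_ids)) - vm.B
    vm.vir = I_minus_B.T @ I_minus_B
    return vm


def knn_laplacian(W: SimilarityNetwork, K: int = 15) -> VicusMatrix:
    """Combinatorial Laplacian of the (mutual-or) K-NN graph of ``W``.

    Drop-in alternative to the Vicus regularizer: shares the symmetric-PSD
    and null-vector-of-ones properties but encodes global degrees instead
    of local diffusion. Returned in the same container with ``B`` holding
    the masked adjacency.
    """
    n = W.n_nodes
    K = min(K, n - 1)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        nbrs, _ = knn_subnetwork(W, i, K)
        mask[i, nbrs] = True
    mask |= mask.T
    adj = np.where(mask, W.matrix, 0.0)
    np.fill_diagonal(adj, 0.0)
    lap = np.diag(adj.sum(axis=1)) - adj
    return VicusMatrix(list(W.node_ids), adj, lap)
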