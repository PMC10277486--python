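"""Weighted K-nearest-known-neighbour profile (WKNNP) smoothing.

The observed interaction matrix is extremely sparse; most zeros are
unobserved rather than verified negatives. Before factorization each zero
entry is softened with an imputed score: a decay-weighted average of the
interaction profiles of the K most similar metabolites (row side) and the
K most similar diseases (column side), combined by the elementwise maximum
with the original matrix so observed interactions are preserved.

For metabolite ``i`` with neighbours ``i_1 .. i_K`` ordered by descending
similarity::

    Ym[i, j] = (1 / Z_i) * sum_k eta**(k-1) * SM[i, i_k] * Y[i_k, j]
    Z_i      = sum_k eta**(k-1) * SM[i, i_k]

and symmetrically ``Yd`` over disease columns. The smoothed matrix is
``D = max(Y, (Ym + Yd) / 2)`` clipped to ``[0, 1]``.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import InteractionMatrix, SimilarityNetwork

__all__ = ["wknnp_smooth", "WKNNPSmoother"]

logger = logging.getLogger(__name__)


def _neighbour_profile(Y: np.ndarray, S: np.ndarray, K: int, eta: float,
                       known_only: bool) -> np.ndarray:
    """One-sided neighbour imputation over the rows of ``Y``."""
    n = Y.shape[0]
    out = np.zeros_like(Y)
    has_interaction = Y.sum(axis=1) > 0
    for i in range(n):
        candidates = np.arange(n)
        mask = candidates != i
        if known_only:
            mask &= has_interaction
        candidates = candidates[mask]
        if candidates.size == 0:
            continue
        sims = S[i, candidates]
        # descending similarity, ties by ascending identifier index
        order = np.lexsort((candidates, -sims))[:K]
        nbrs = candidates[order]
        w = eta ** np.arange(len(nbrs)) * S[i, nbrs]
        z = w.sum()
        if z <= 0:
            logger.debug("WKNNP: zero neighbour weight for row %d; left as is", i)
            continue
        out[i] = (w @ Y[nbrs]) / z
    return out


def wknnp_smooth(Y: InteractionMatrix, met_sim: SimilarityNetwork,
                 dis_sim: SimilarityNetwork, K: int = 5, eta: float = 0.9,
                 known_only: bool = True) -> InteractionMatrix:
    """Smooth an interaction matrix by two-sided neighbour imputation.

    Parameters
    ----------
    Y
        Interaction matrix (rows metabolites, columns diseases).
    met_sim, dis_sim
        Similarity networks aligned with the rows and columns of ``Y``.
    K
        Number of neighbours per node.
    eta
        Geometric decay in ``(0, 1)`` down the neighbour ranking.
    known_only
        Restrict neighbours to nodes with at least one observed interaction.

    Returns
    -------
    InteractionMatrix
        Real-valued smoothed matrix; never below the input elementwise.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 < eta <= 1.0:
        raise ValueError("eta must lie in (0, 1]")
    Y.check_aligned(met_sim, dis_sim)
    A = Y.values
    Ym = _neighbour_profile(A, met_sim.matrix, K, eta, known_only)
    Yd = _neighbour_profile(A.T, dis_sim.matrix, K, eta, known_only).T
    D = np.maximum(A, (Ym + Yd) / 2.0)
    D = np.clip(D, 0.0, 1.0)
    return InteractionMatrix(list(Y.metabolite_ids), list(Y.disease_ids), D,
                             binary=False)


class WKNNPSmoother:
    """Transformer-style wrapper around :func:`wknnp_smooth`.

    Follows the scikit-learn transformer protocol loosely: the similarity
    networks are constructor state, ``transform`` maps an interaction matrix
    to its smoothed counterpart. There is nothing to fit.
    """

    def __init__(self, met_sim: SimilarityNetwork, dis_sim: SimilarityNetwork,
                 K: int = 5, eta: float = 0.9, known_only: bool = True):
        self.met_sim = met_sim
        self.dis_sim = dis_sim
        self.K = K
        self.eta = eta
        self.known_only = known_only

    def get_params(self, deep: bool = True) -> dict:
        return {"met_sim": self.met_sim, "dis_sim": self.dis_sim,
                "K": self.K, "eta": self.eta, "known_only": self.known_only}

    def set_params(self, **params) -> "WKNNPSmoother":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, Y: InteractionMatrix | None = None) -> "WKNNPSmoother":
        return self

    def transform(self, Y: InteractionMatrix) -> InteractionMatrix:
        return wknnp_smooth(Y, self.met_sim, self.dis_sim, K=self.K,
                            eta=self.eta, known_only=self.known_only)

    def fit_transform(self, Y: InteractionMatrix) -> InteractionMatrix:
        return self.transform(Y)
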