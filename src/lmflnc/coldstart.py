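"""Cold-start latent projection and pair scoring.

Latent vectors of metabolites (or diseases) with no observed interaction
are learned purely from negative evidence and are unreliable. They are
replaced by a decay-weighted combination of the latent vectors of the K
most similar *interacting* neighbours::

    u_bar_i = (1 / Q_i) * sum_k alpha**(k-1) * cons[i, n_k] * u_{n_k}
    Q_i     = sum_k alpha**(k-1) * cons[i, n_k]

where ``cons`` is the similarity matrix masked to mutual-or-one-sided
K-nearest-neighbour pairs and neighbours ``n_k`` are ordered by descending
masked similarity. Interacting nodes keep their trained vectors, and the
final score of a pair is the logistic of the projected inner product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InteractionMatrix, SimilarityNetwork
from .lmf import LMFLNC, interaction_probability

__all__ = [
    "NeighborConstraintGraph",
    "known_node_set",
    "build_constraint_graph",
    "project_latent",
    "project_model",
    "predict_pair",
    "rank_for_disease",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborConstraintGraph:
    """K-NN-masked similarity matrix with decay parameters."""

    node_ids: list[str]
    cons: np.ndarray
    K_proj: int = 10
    alpha_decay: float = 0.9


def known_node_set(A: InteractionMatrix | np.ndarray,
                   axis: str = "metabolites") -> np.ndarray:
    """Indices of nodes with at least one observed interaction.

    Computed from the original binary matrix, not the smoothed one (after
    smoothing nearly every profile is nonzero and nothing would count as
    cold).
    """
    vals = A.values if isinstance(A, InteractionMatrix) else np.asarray(A)
    if axis == "metabolites":
        sums = vals.sum(axis=1)
    elif axis == "diseases":
        sums = vals.sum(axis=0)
    else:
        raise ValueError("axis must be 'metabolites' or 'diseases'")
    return np.nonzero(sums > 0)[0]


def build_constraint_graph(S: SimilarityNetwork, K_proj: int = 10,
                           alpha_decay: float = 0.9) -> NeighborConstraintGraph:
    """Mask ``S`` to pairs where either node is among the other's K nearest.

    The or-rule makes the mask symmetric by construction.
    """
    if not 0.0 < alpha_decay < 1.0:
        raise ValueError("alpha_decay must lie in (0, 1)")
    n = S.n_nodes
    K = min(K_proj, n - 1)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        order = np.lexsort((others, -S.matrix[i, others]))
        mask[i, others[order[:K]]] = True
    mask |= mask.T
    cons = np.where(mask, S.matrix, 0.0)
    return NeighborConstraintGraph(list(S.node_ids), cons, K, alpha_decay)


def project_latent(factors: np.ndarray, graph: NeighborConstraintGraph,
                   known: np.ndarray) -> np.ndarray:
    """Replace cold-node rows of a latent matrix by neighbour combinations.

    Parameters
    ----------
    factors
        Latent matrix (one row per node) from the trained model.
    graph
        Constraint graph over the same node set.
    known
        Indices of interacting nodes; only their vectors may be borrowed.

    Returns a new matrix; rows of known nodes are unchanged, and a cold
    node whose masked similarity to every known node is zero keeps its
    trained vector (with a logged warning).
    """
    factors = np.asarray(factors, dtype=float)
    n = factors.shape[0]
    if graph.cons.shape != (n, n):
        raise ValueError("constraint graph does not match latent matrix size")
    known = np.asarray(known, dtype=int)
    known_mask = np.zeros(n, dtype=bool)
    known_mask[known] = True
    out = factors.copy()
    for i in range(n):
        if known_mask[i]:
            continue
        cand = known[graph.cons[i, known] > 0]
        if cand.size == 0:
            logger.warning("cold node %d has no similar interacting "
                           "neighbour; keeping trained vector", i)
            continue
        order = np.lexsort((cand, -graph.cons[i, cand]))
        nbrs = cand[order[:graph.K_proj]]
        w = graph.alpha_decay ** np.arange(len(nbrs)) * graph.cons[i, nbrs]
        q = w.sum()
        if q <= 0:
            logger.warning("cold node %d: zero normalization; keeping "
                           "trained vector", i)
            continue
        out[i] = (w @ factors[nbrs]) / q
    return out


def predict_pair(U_bar: np.ndarray, V_bar: np.ndarray, i: int, j: int) -> float:
    """Interaction probability of metabolite ``i`` and disease ``j`` after
    projection."""
    return interaction_probability(U_bar[i], V_bar[j])


def project_model(model: LMFLNC, A_binary: InteractionMatrix | np.ndarray,
                  met_sim: SimilarityNetwork, dis_sim: SimilarityNetwork,
                  K_proj: int = 10, alpha_decay: float = 0.9,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: project both factor matrices of a fitted model."""
    gm = build_constraint_graph(met_sim, K_proj, alpha_decay)
    gd = build_constraint_graph(dis_sim, K_proj, alpha_decay)
    U_bar = project_latent(model.U_, gm, known_node_set(A_binary, "metabolites"))
    V_bar = project_latent(model.V_, gd, known_node_set(A_binary, "diseases"))
    return U_bar, V_bar


def rank_for_disease(U_bar: np.ndarray, V_bar: np.ndarray,
                     A_train: InteractionMatrix, disease_id: str,
                     top_k: int = 15) -> pd.DataFrame:
    """Rank all metabolites for one disease by predicted probability.

    Returns a table with columns rank, metabolite_id, probability and a
    known/unknown flag against the training matrix; descending probability,
    ties broken by metabolite identifier.
    """
    try:
        j = A_train.disease_ids.index(str(disease_id))
    except ValueError:
        raise KeyError(f"unknown disease identifier: {disease_id!r}") from None
    from .lmf import _sigmoid  # stable logistic
    probs = np.asarray(_sigmoid(U_bar @ V_bar[j]), dtype=float)
    df = pd.DataFrame({
        "metabolite_id": A_train.metabolite_ids,
        "probability": probs,
        "category": np.where(A_train.values[:, j] > 0, "known", "unknown"),
    })
    df = df.sort_values(["probability", "metabolite_id"],
                        ascending=[False, True], kind="mergesort")
    df = df.head(min(top_k, len(df))).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
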