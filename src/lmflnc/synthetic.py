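"""Synthetic data generators for desk-scale experiments.

The model assumes that interactions concentrate among similar metabolites
and similar diseases. The bipartite generator plants exactly that
structure: metabolites and diseases are assigned to latent blocks,
interactions are dense within matched blocks and sparse elsewhere, and the
similarity networks echo block identity through elevated within-block
means. Separate fixtures generate toy term hierarchies and gene-annotation
tables so the similarity-construction code is exercised end to end without
any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import InteractionMatrix, SimilarityNetwork
from .similarity import GeneAnnotationTable, TermDag

__all__ = [
    "SyntheticSpec",
    "generate_bipartite",
    "generate_toy_dag",
    "generate_annotations",
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block bipartite generator.

    ``similarity_signal`` is the gap between the within-block and
    between-block mean similarity; at 0 the similarity networks carry no
    block information (negative control).
    """

    n_metabolites: int = 20
    n_diseases: int = 15
    n_blocks: int = 2
    within_block_interaction_prob: float = 0.9
    background_interaction_prob: float = 0.05
    noise_flip_prob: float = 0.05
    similarity_signal: float = 0.6
    similarity_base: float = 0.2
    similarity_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_block_interaction_prob",
                     "background_interaction_prob", "noise_flip_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must lie in [0, 1]")
        if self.n_blocks > min(self.n_metabolites, self.n_diseases):
            raise ValueError("more blocks than nodes on one side")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous, nearly equal block assignment."""
    return np.sort(np.arange(n) % n_blocks)


def _block_similarity(labels: np.ndarray, spec: SyntheticSpec,
                      rng: np.random.Generator) -> np.ndarray:
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    mean = np.where(same, spec.similarity_base + spec.similarity_signal,
                    spec.similarity_base)
    raw = rng.normal(mean, spec.similarity_sd)
    sym = (raw + raw.T) / 2.0
    sym = np.clip(sym, 0.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return sym


def generate_bipartite(spec: SyntheticSpec | None = None,
                       ) -> tuple[InteractionMatrix, SimilarityNetwork,
                                  SimilarityNetwork, dict]:
    """Generate a planted-block interaction matrix and matched similarity
    networks.

    Returns the binary interaction matrix, metabolite and disease
    similarity networks, and the ground-truth block labels
    ``{"metabolites": ..., "diseases": ...}``. Fully reproducible from
    ``spec.seed``.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    mlab = _block_labels(spec.n_metabolites, spec.n_blocks)
    dlab = _block_labels(spec.n_diseases, spec.n_blocks)
    same = mlab[:, None] == dlab[None, :]
    prob = np.where(same, spec.within_block_interaction_prob,
                    spec.background_interaction_prob)
    A = (rng.random(prob.shape) < prob).astype(float)
    flips = rng.random(A.shape) < spec.noise_flip_prob
    A = np.where(flips, 1.0 - A, A)
    met_ids = [f"M{i:03d}" for i in range(spec.n_metabolites)]
    dis_ids = [f"D{j:03d}" for j in range(spec.n_diseases)]
    met_sim = SimilarityNetwork(met_ids, _block_similarity(mlab, spec, rng))
    dis_sim = SimilarityNetwork(dis_ids, _block_similarity(dlab, spec, rng))
    interactions = InteractionMatrix(met_ids, dis_ids, A, binary=True)
    labels = {"metabolites": mlab, "diseases": dlab}
    return interactions, met_sim, dis_sim, labels


def generate_toy_dag(depth: int = 3, branching: int = 2, seed: int = 0,
                     extra_parent_prob: float = 0.0,
                     max_self_count: int = 5) -> TermDag:
    """Random rooted term hierarchy with per-term annotation counts.

    A complete tree of the given depth and branching factor; with
    ``extra_parent_prob > 0`` additional cross edges from shallower terms
    give some terms two parents (diamonds) while keeping the graph acyclic.
    Self counts are uniform in ``[1, max_self_count]``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []   # (child, parent)
    levels: list[list[str]] = [["T0"]]
    counter = 1
    for d in range(1, depth):
        level = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                child = f"T{counter}"
                counter += 1
                edges.append((child, parent))
                level.append(child)
        levels.append(level)
    if extra_parent_prob > 0:
        for d in range(2, depth):
            for child in levels[d]:
                if rng.random() < extra_parent_prob:
                    extra = levels[d - 1][rng.integers(len(levels[d - 1]))]
                    if (child, extra) not in edges:
                        edges.append((child, extra))
    terms = [t for level in levels for t in level]
    counts = {t: int(rng.integers(1, max_self_count + 1)) for t in terms}
    return TermDag.from_edges(edges, counts)


def generate_annotations(n_genes: int = 8, n_go: int = 10,
                         n_metabolites: int = 5, seed: int = 0,
                         ) -> GeneAnnotationTable:
    """Random gene-GO and metabolite-gene tables; every metabolite and gene
    gets a nonempty set."""
    if min(n_genes, n_go, n_metabolites) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    gos = [f"GO:{i:04d}" for i in range(n_go)]
    go_sets = {}
    for g in genes:
        size = min(n_go, int(rng.integers(1, max(2, n_go // 2) + 1)))
        go_sets[g] = frozenset(rng.choice(gos, size=size, replace=False))
    met_genes = {}
    for k in range(n_metabolites):
        size = min(n_genes, int(rng.integers(1, max(2, n_genes // 2) + 1)))
        met_genes[f"M{k:03d}"] = frozenset(
            rng.choice(genes, size=size, replace=False))
    return GeneAnnotationTable(go_sets, met_genes)
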