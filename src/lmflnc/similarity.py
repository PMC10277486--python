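"""Similarity-network construction.

Two sources feed the model:

* **Disease semantic similarity** from a rooted term hierarchy (a MeSH-style
  DAG) with per-term annotation counts, scored with Lin's
  information-content measure: ``score(t1, t2) = max_{t in CA(t1,t2)}
  2 log p(t) / (log p(t1) + log p(t2))`` where ``p(t)`` is the annotation
  frequency of ``t`` relative to the root.

* **Metabolite functional similarity** from metabolite-gene links and
  gene-GO annotations: genes are compared by the Jaccard index of their GO
  sets, and two metabolites by the best-match average of their gene sets.

Heterogeneous disease networks (hierarchy-based, gene-based, GO-based) are
combined by configurable weighted averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import SimilarityNetwork

__all__ = [
    "TermDag",
    "GeneAnnotationTable",
    "term_frequency",
    "term_probability",
    "lin_similarity",
    "disease_similarity_matrix",
    "gene_go_jaccard",
    "gene_set_similarity",
    "metabolite_similarity",
    "metabolite_similarity_matrix",
    "fuse_similarities",
]

logger = logging.getLogger(__name__)


class TermDagError(ValueError):
    pass


@dataclass
class TermDag:
    """Rooted DAG of disease terms with per-term annotation counts.

    Edges point downwards (parent -> child). A term's frequency ``f(t)`` is
    the total annotation count over the set of terms at or below ``t``; on a
    multi-parent (diamond) DAG each descendant is counted once, via the
    descendant-set union, so that ``f(t) <= f(root)`` and probabilities stay
    in ``(0, 1]``.
    """

    graph: nx.DiGraph            # parent -> child
    self_counts: dict[str, int]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise TermDagError("term hierarchy contains a cycle")
        roots = [t for t in self.graph if self.graph.in_degree(t) == 0]
        if len(roots) != 1:
            raise TermDagError(f"expected exactly one root term, found {roots}")
        self.root = roots[0]
        for t in self.graph:
            if self.self_counts.get(t, 0) < 0:
                raise TermDagError(f"negative annotation count for term {t!r}")

    @classmethod
    def from_edges(cls, parent_edges: Iterable[tuple[str, str]],
                   self_counts: Mapping[str, int]) -> "TermDag":
        """Build from (child, parent) pairs and a term -> count mapping."""
        g = nx.DiGraph()
        for child, parent in parent_edges:
            g.add_edge(str(parent), str(child))
        for t in self_counts:
            g.add_node(str(t))
        return cls(g, {str(t): int(c) for t, c in self_counts.items()})

    @classmethod
    def from_tsv(cls, hierarchy_path: str | Path,
                 counts_path: str | Path) -> "TermDag":
        edges = pd.read_csv(hierarchy_path, sep="\t", dtype=str)
        counts = pd.read_csv(counts_path, sep="\t", dtype={0: str})
        mapping = dict(zip(counts.iloc[:, 0], counts.iloc[:, 1].astype(int)))
        return cls.from_edges(
            zip(edges.iloc[:, 0], edges.iloc[:, 1]), mapping)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def _require(self, t: str) -> None:
        if t not in self.graph:
            raise KeyError(f"unknown term identifier: {t!r}")

    def self_count(self, t: str) -> int:
        self._require(t)
        return int(self.self_counts.get(t, 0))

    def ancestors_or_self(self, t: str) -> set[str]:
        self._require(t)
        return nx.ancestors(self.graph, t) | {t}

    def descendants_or_self(self, t: str) -> set[str]:
        self._require(t)
        return nx.descendants(self.graph, t) | {t}


def term_frequency(dag: TermDag, t: str) -> int:
    """Annotation frequency of term ``t``: its own count plus the counts of
    every term below it, each descendant counted once."""
    return sum(dag.self_count(s) for s in dag.descendants_or_self(t))


def term_probability(dag: TermDag, t: str) -> float:
    """Frequency of ``t`` relative to the root; 1.0 at the root."""
    n = term_frequency(dag, dag.root)
    if n == 0:
        raise TermDagError("root term frequency is zero: DAG has no annotations")
    return term_frequency(dag, t) / n


def lin_similarity(dag: TermDag, t1: str, t2: str) -> float:
    """Lin information-content similarity of two terms in ``[0, 1]``.

    The maximum is taken over all common ancestors; because the probability
    is nondecreasing towards the root, the optimum is always attained at a
    least common ancestor. A term with probability 1 (the root) carries no
    information content and scores 0 against any other term, 1 against
    itself.
    """
    p1 = term_probability(dag, t1)
    p2 = term_probability(dag, t2)
    if t1 == t2:
        return 1.0
    if p1 >= 1.0 or p2 >= 1.0:
        return 0.0
    common = dag.ancestors_or_self(t1) & dag.ancestors_or_self(t2)
    if not common:
        return 0.0
    denom = math.log(p1) + math.log(p2)
    best = max(2.0 * math.log(term_probability(dag, t)) / denom for t in common)
    return min(max(best, 0.0), 1.0)


def disease_similarity_matrix(dag: TermDag,
                              diseases: Sequence[str]) -> SimilarityNetwork:
    """Pairwise Lin similarity over a list of disease terms."""
    missing = [d for d in diseases if d not in dag.graph]
    if missing:
        raise KeyError(f"diseases not present in the term hierarchy: {missing}")
    n = len(diseases)
    # probabilities computed once; the pair loop reuses ancestor sets
    freq = {t: term_frequency(dag, t) for t in dag.graph}
    n_root = freq[dag.root]
    if n_root == 0:
        raise TermDagError("root term frequency is zero: DAG has no annotations")
    logp = {t: math.log(freq[t] / n_root) if freq[t] < n_root else 0.0
            for t in dag.graph}
    anc = {d: dag.ancestors_or_self(d) for d in diseases}
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = diseases[i], diseases[j]
            if ti == tj:
                mat[i, j] = mat[j, i] = 1.0
                continue
            if logp[ti] == 0.0 or logp[tj] == 0.0:
                continue
            common = anc[ti] & anc[tj]
            denom = logp[ti] + logp[tj]
            score = max((2.0 * logp[t] / denom for t in common), default=0.0)
            mat[i, j] = mat[j, i] = min(max(score, 0.0), 1.0)
    return SimilarityNetwork([str(d) for d in diseases], mat)


# ---------------------------------------------------------------------------
# Metabolite functional similarity
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotationTable:
    """Gene -> GO-term sets plus metabolite -> gene sets."""

    go_sets: dict[str, frozenset[str]]
    metabolite_genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.go_sets = {str(g): frozenset(map(str, s))
                        for g, s in self.go_sets.items()}
        self.metabolite_genes = {str(m): frozenset(map(str, s))
                                 for m, s in self.metabolite_genes.items()}

    @classmethod
    def from_tsv(cls, gene_go_path: str | Path,
                 metabolite_gene_path: str | Path) -> "GeneAnnotationTable":
        gg = pd.read_csv(gene_go_path, sep="\t", dtype=str)
        mg = pd.read_csv(metabolite_gene_path, sep="\t", dtype=str)
        go_sets: dict[str, set[str]] = {}
        for g, go in zip(gg.iloc[:, 0], gg.iloc[:, 1]):
            go_sets.setdefault(g, set()).add(go)
        met_genes: dict[str, set[str]] = {}
        for m, g in zip(mg.iloc[:, 0], mg.iloc[:, 1]):
            met_genes.setdefault(m, set()).add(g)
            go_sets.setdefault(g, set())
        return cls({g: frozenset(s) for g, s in go_sets.items()},
                   {m: frozenset(s) for m, s in met_genes.items()})

    def gene_ids(self) -> list[str]:
        return sorted(self.go_sets)

    def genes_of(self, metabolite: str) -> frozenset[str]:
        try:
            genes = self.metabolite_genes[str(metabolite)]
        except KeyError:
            raise KeyError(f"unknown metabolite identifier: {metabolite!r}") from None
        if not genes:
            raise ValueError(
                f"metabolite {metabolite!r} has no mapped genes and must be "
                "excluded from functional-similarity computation")
        return genes

    def annotated_metabolites(self) -> list[str]:
        """Metabolites with at least one mapped gene; others are reported."""
        keep, dropped = [], []
        for m in sorted(self.metabolite_genes):
            (keep if self.metabolite_genes[m] else dropped).append(m)
        if dropped:
            logger.warning(
                "dropping %d metabolites without gene mappings: %s",
                len(dropped), dropped)
        return keep


def gene_go_jaccard(a: str, b: str, table: GeneAnnotationTable) -> float:
    """Jaccard index of two genes' GO sets; 0 when both are unannotated."""
    for g in (a, b):
        if str(g) not in table.go_sets:
            raise KeyError(f"unknown gene identifier: {g!r}")
    sa, sb = table.go_sets[str(a)], table.go_sets[str(b)]
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def gene_set_similarity(g: str, genes: Iterable[str],
                        table: GeneAnnotationTable) -> float:
    """Best GO-Jaccard match of gene ``g`` against a nonempty gene set."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene set must be nonempty")
    return max(gene_go_jaccard(g, other, table) for other in genes)


def metabolite_similarity(m1: str, m2: str, table: GeneAnnotationTable) -> float:
    """Best-match-average similarity of two metabolites' gene sets."""
    g1, g2 = table.genes_of(m1), table.genes_of(m2)
    total = sum(gene_set_similarity(g, g2, table) for g in sorted(g1))
    total += sum(gene_set_similarity(g, g1, table) for g in sorted(g2))
    return total / (len(g1) + len(g2))


def metabolite_similarity_matrix(table: GeneAnnotationTable,
                                 metabolites: Sequence[str] | None = None,
                                 ) -> SimilarityNetwork:
    """Pairwise functional similarity over annotated metabolites."""
    if metabolites is None:
        metabolites = table.annotated_metabolites()
    mets = [str(m) for m in metabolites]
    n = len(mets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = metabolite_similarity(mets[i], mets[j], table)
            mat[i, j] = mat[j, i] = s
    return SimilarityNetwork(mets, np.clip(mat, 0.0, 1.0))


def fuse_similarities(networks: Sequence[SimilarityNetwork],
                      weights: Sequence[float] | None = None,
                      ) -> SimilarityNetwork:
    """Weighted elementwise average of similarity networks over one node set."""
    if not networks:
        raise ValueError("need at least one network to fuse")
    ids = networks[0].node_ids
    for net in networks[1:]:
        if net.node_ids != ids:
            raise ValueError("cannot fuse networks with different node sets")
    if weights is None:
        weights = [1.0] * len(networks)
    w = np.asarray(list(weights), dtype=float)
    if len(w) != len(networks) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with a positive sum")
    w = w / w.sum()
    fused = sum(wk * net.matrix for wk, net in zip(w, networks))
    return SimilarityNetwork(list(ids), fused)
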