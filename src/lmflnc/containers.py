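"""Core data containers: interaction matrices and similarity networks.

Both containers pair a dense :class:`numpy.ndarray` with ordered identifier
registries so that rows/columns of the interaction matrix stay aligned with
the metabolite and disease similarity networks used alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SimilarityNetwork", "InteractionMatrix", "AlignmentError"]

_SYMMETRY_TOL = 1e-10


class AlignmentError(ValueError):
    """Raised when identifier registries of two containers do not match."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes}")
    return ids


@dataclass
class SimilarityNetwork:
    """Symmetric nonnegative similarity matrix over one node set.

    Parameters
    ----------
    node_ids
        Ordered node identifiers; row/column ``k`` of ``matrix`` refers to
        ``node_ids[k]``.
    matrix
        Square symmetric array with entries in ``[0, 1]``.
    """

    node_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = _check_unique(self.node_ids, "node")
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.node_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} node ids"
            )
        asym = np.max(np.abs(self.matrix - self.matrix.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix is not symmetric (max asymmetry {asym:g})")
        if n and (self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self._index = {nid: k for k, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node identifier: {node_id!r}") from None

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=self.node_ids, columns=self.node_ids)
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(i) for i in df.index]
        if [str(c) for c in df.columns] != ids:
            raise ValueError("row and column identifiers differ in similarity TSV")
        return cls(ids, df.to_numpy(dtype=float))


@dataclass
class InteractionMatrix:
    """Metabolite x disease association matrix.

    Binary (``{0, 1}``) before neighbour smoothing, real-valued in ``[0, 1]``
    afterwards. Rows are metabolites, columns diseases.
    """

    metabolite_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray
    binary: bool = field(default=True)

    def __post_init__(self) -> None:
        self.metabolite_ids = _check_unique(self.metabolite_ids, "metabolite")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.metabolite_ids), len(self.disease_ids))
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != {shape}")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("interaction values must lie in [0, 1]")
        if self.binary and self.values.size:
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError("binary interaction matrix has non {0,1} entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            list(self.metabolite_ids),
            list(self.disease_ids),
            self.values.copy(),
            binary=self.binary,
        )

    def check_aligned(self, met_sim: SimilarityNetwork | None = None,
                      dis_sim: SimilarityNetwork | None = None) -> None:
        if met_sim is not None and met_sim.node_ids != self.metabolite_ids:
            raise AlignmentError("metabolite similarity network not aligned with rows")
        if dis_sim is not None and dis_sim.node_ids != self.disease_ids:
            raise AlignmentError("disease similarity network not aligned with columns")

    # -- TSV dialects ------------------------------------------------------

    def to_edge_tsv(self, path: str | Path) -> None:
        """Write the nonzero entries as (metabolite_id, disease_id, value)."""
        rows, cols = np.nonzero(self.values)
        df = pd.DataFrame(
            {
                "metabolite_id": [self.metabolite_ids[i] for i in rows],
                "disease_id": [self.disease_ids[j] for j in cols],
                "value": self.values[rows, cols],
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_edge_tsv(cls, path: str | Path,
                      metabolite_ids: Sequence[str] | None = None,
                      disease_ids: Sequence[str] | None = None,
                      ) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(df.columns)
        if len(cols) == 2:
            df["value"] = 1.0
        mets = (list(metabolite_ids) if metabolite_ids is not None
                else sorted(df.iloc[:, 0].unique()))
        dis = (list(disease_ids) if disease_ids is not None
               else sorted(df.iloc[:, 1].unique()))
        mi = {m: k for k, m in enumerate(mets)}
        di = {d: k for k, d in enumerate(dis)}
        vals = np.zeros((len(mets), len(dis)))
        for m, d, v in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
            if m not in mi:
                raise KeyError(f"edge references unknown metabolite {m!r}")
            if d not in di:
                raise KeyError(f"edge references unknown disease {d!r}")
            vals[mi[m], di[d]] = float(v)
        binary = bool(np.all(np.isin(vals, (0.0, 1.0))))
        return cls(mets, dis, vals, binary=binary)

    def to_dense_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.metabolite_ids,
                          columns=self.disease_ids)
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_dense_tsv(cls, path: str | Path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy(dtype=float)
        binary = bool(np.all(np.isin(vals, (0.0, 1.0))))
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   vals, binary=binary)
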