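"""Core in-memory containers shared by all stages of the pipeline.

The association data is a binary bipartite matrix ``A`` with diseases on the
rows and microbes on the columns; every other container (similarity matrices,
the heterogeneous graph, score matrices) carries the same ordered labels so
that results can always be traced back to entity identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "HeteroGraph",
    "ScoreMatrix",
    "SampleSets",
]

_SYM_TOL = 1e-12


def _check_unique(labels: Sequence[str], what: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    return labels


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary disease x microbe association matrix with ordered labels."""

    values: np.ndarray
    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "disease_ids", _check_unique(self.disease_ids, "disease")
        )
        object.__setattr__(
            self, "microbe_ids", _check_unique(self.microbe_ids, "microbe")
        )
        nd, nm = values.shape
        if nd != len(self.disease_ids) or nm != len(self.microbe_ids):
            raise ValueError("label count does not match matrix shape")
        if nd < 1 or nm < 1:
            raise ValueError("matrix must have at least one row and column")

    @property
    def n_diseases(self) -> int:
        return self.values.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """Same labels, new binary values (used to mask cells for CV)."""
        return AssociationMatrix(values, self.disease_ids, self.microbe_ids)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] over one entity type.

    ``kind`` records how the matrix was produced: a Gaussian interaction
    profile kernel (``gip``), a best-match-average functional similarity
    (``functional``), or the conditional fusion of the two (``integrated``).
    """

    values: np.ndarray
    entity_ids: tuple[str, ...]
    kind: str = "gip"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if values.shape[0] != len(self.entity_ids):
            raise ValueError("label count does not match matrix shape")
        if not np.allclose(values, values.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("similarity matrix must be symmetric")
        if values.min() < -_SYM_TOL or values.max() > 1.0 + _SYM_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.kind not in ("gip", "functional", "integrated", "normalized"):
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "entity_ids", _check_unique(self.entity_ids, "entity")
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class HeteroGraph:
    """Heterogeneous disease+microbe graph.

    ``adjacency`` is the (nd+nm) x (nd+nm) block matrix
    ``[[beta * DS*, A], [A^T, beta * MS*]]`` and ``h0`` the fixed initial
    feature matrix ``[[0, A], [A^T, 0]]``; node order is diseases first.
    """

    adjacency: np.ndarray
    h0: np.ndarray
    n_diseases: int
    n_microbes: int
    node_ids: tuple[str, ...]
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        h0 = np.asarray(self.h0, dtype=float)
        n = self.n_diseases + self.n_microbes
        if adj.shape != (n, n) or h0.shape != (n, n):
            raise ValueError("adjacency/h0 shape does not match node count")
        if not np.allclose(adj, adj.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("heterogeneous adjacency must be symmetric")
        degrees = adj.sum(axis=1)
        if (degrees <= 0).any():
            raise ValueError("zero-degree node in heterogeneous graph")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "h0", h0)
        object.__setattr__(self, "degrees", degrees)

    @property
    def n_nodes(self) -> int:
        return self.n_diseases + self.n_microbes

    def normalized_adjacency(self) -> np.ndarray:
        """D^{-1/2} G D^{-1/2} used by every propagation step."""
        d_inv_sqrt = 1.0 / np.sqrt(self.degrees)
        return self.adjacency * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted association scores, strictly inside (0, 1)."""

    values: np.ndarray
    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.disease_ids), len(self.microbe_ids)):
            raise ValueError("label count does not match score shape")
        if values.min() <= 0.0 or values.max() >= 1.0:
            raise ValueError("scores must lie strictly in (0, 1)")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class SampleSets:
    """Positive and negative training cells (row, col) of the matrix."""

    positives: frozenset[tuple[int, int]]
    negatives: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positive and negative sample sets overlap")

    @classmethod
    def from_matrix(cls, values: np.ndarray) -> "SampleSets":
        values = np.asarray(values)
        pos = frozenset(zip(*np.nonzero(values == 1)))
        neg = frozenset(zip(*np.nonzero(values == 0)))
        return cls(frozenset((int(i), int(j)) for i, j in pos),
                   frozenset((int(i), int(j)) for i, j in neg))
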