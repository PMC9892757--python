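"""Heterogeneous graph assembly and the symmetric-normalized propagation.

The disease similarity block and the microbe similarity block are first
degree-normalized, scaled by a penalty factor ``beta`` controlling how much
the similarity edges contribute relative to the association edges, and then
placed on the diagonal of a 2x2 block adjacency with the association matrix
off-diagonal.  The initial node features are the association blocks alone.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AssociationMatrix, HeteroGraph, SimilarityMatrix

__all__ = ["normalize_block", "build_hetnet", "sym_norm_propagate"]


def normalize_block(S: SimilarityMatrix, method: str = "sym_degree") -> SimilarityMatrix:
    """Normalize a similarity block before graph assembly.

    ``sym_degree`` (default) applies the symmetric degree normalization
    Ds^{-1/2} S Ds^{-1/2}, bounding the spectral radius by 1; ``max``
    divides by the largest entry instead.
    """
    V = S.values
    if method == "sym_degree":
        row_sums = V.sum(axis=1)
        if (row_sums <= 0).any():
            raise ValueError("zero row sum: cannot degree-normalize")
        d = 1.0 / np.sqrt(row_sums)
        out = V * d[:, None] * d[None, :]
    elif method == "max":
        m = V.max()
        if m <= 0:
            raise ValueError("all-zero similarity block")
        out = V / m
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    out = 0.5 * (out + out.T)
    return SimilarityMatrix(out, S.entity_ids, kind="normalized")


def build_hetnet(
    DS_star: SimilarityMatrix,
    MS_star: SimilarityMatrix,
    A: AssociationMatrix,
    beta: float,
) -> HeteroGraph:
    """Assemble the block adjacency [[beta*DS*, A], [A^T, beta*MS*]] and the
    fixed initial features [[0, A], [A^T, 0]] (diseases first)."""
    nd, nm = A.values.shape
    if DS_star.n != nd or MS_star.n != nm:
        raise ValueError("similarity block dimensions do not match A")
    if beta <= 0:
        raise ValueError("beta must be positive")
    n = nd + nm
    adj = np.zeros((n, n))
    adj[:nd, :nd] = beta * DS_star.values
    adj[nd:, nd:] = beta * MS_star.values
    adj[:nd, nd:] = A.values
    adj[nd:, :nd] = A.values.T
    h0 = np.zeros((n, n))
    h0[:nd, nd:] = A.values
    h0[nd:, :nd] = A.values.T
    node_ids = tuple(A.disease_ids) + tuple(A.microbe_ids)
    return HeteroGraph(adj, h0, nd, nm, node_ids)


def sym_norm_propagate(G: HeteroGraph, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph-convolution step: tanh(D^{-1/2} G D^{-1/2} H W)."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.shape[0] != G.n_nodes:
        raise ValueError("feature matrix row count does not match graph")
    if W.shape[0] != H.shape[1]:
        raise ValueError("weight matrix inner dimension mismatch")
    return np.tanh(G.normalized_adjacency() @ H @ W)
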