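"""Heterogeneous circRNA-disease network assembly.

Nodes are ordered circRNAs first (indices ``0..nc-1``) then diseases
(``nc..nc+nd-1``). The adjacency ``M`` carries only cross-type association
edges, ``M = [[0, A], [A^T, 0]]``; within-type similarity enters through
the block-diagonal feature matrix ``X = blockdiag(mu*SC, mu*SD)``, where
the penalty factor ``mu`` (default 0.6) scales the similarity contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class HetGraph:
    M: np.ndarray  # (nc+nd) x (nc+nd) binary, symmetric, zero diagonal blocks
    X: np.ndarray  # (nc+nd) x (nc+nd) block-diagonal features
    nc: int
    nd: int
    mu: float

    @property
    def n_nodes(self) -> int:
        return self.nc + self.nd

    def circ_index(self, i: int) -> int:
        if not 0 <= i < self.nc:
            raise IndexError(f"circRNA index {i} out of range")
        return i

    def dis_index(self, j: int) -> int:
        if not 0 <= j < self.nd:
            raise IndexError(f"disease index {j} out of range")
        return self.nc + j


def build_hetgraph(SC: np.ndarray, SD: np.ndarray, A: np.ndarray, mu: float = 0.6) -> HetGraph:
    """Assemble adjacency and features from the two feature matrices (RWR
    output or fused similarities) and the binary association matrix."""
    SC, SD, A = (np.asarray(m, dtype=float) for m in (SC, SD, A))
    nc, nd = A.shape
    if SC.shape != (nc, nc) or SD.shape != (nd, nd):
        raise ValueError(
            f"shape mismatch: A is {A.shape}, SC {SC.shape}, SD {SD.shape}"
        )
    if not 0 < mu <= 1:
        raise ValueError("mu must be in (0, 1]")
    n = nc + nd
    M = np.zeros((n, n), dtype=np.int8)
    M[:nc, nc:] = A != 0
    M[nc:, :nc] = (A != 0).T
    X = np.zeros((n, n))
    X[:nc, :nc] = mu * SC
    X[nc:, nc:] = mu * SD
    return HetGraph(M=M, X=X, nc=nc, nd=nd, mu=mu)


def mask_test_edges(G: HetGraph, held_out: list[tuple[int, int]]) -> HetGraph:
    """Copy of ``G`` with each held-out (circRNA, disease) edge removed
    symmetrically from ``M``; features are untouched. A pair that is not a
    present edge raises ``ValueError``."""
    M = G.M.copy()
    for i, j in held_out:
        r, c = G.circ_index(i), G.dis_index(j)
        if M[r, c] == 0:
            raise ValueError(f"held-out pair ({i}, {j}) is not an edge")
        M[r, c] = 0
        M[c, r] = 0
    return replace(G, M=M, X=G.X.copy())
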