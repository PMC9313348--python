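"""Similarity kernels for circRNAs and diseases.

Three kernels feed the model:

* **sequence similarity** between circRNAs, ``1 - LevDis(s1, s2) /
  (len(s1) + len(s2))`` from the unit-cost Levenshtein edit distance;
* **semantic similarity** between disease ontology terms, the Wang
  shared-ancestor construction: each term contributes to itself with
  score 1 and to each proper ancestor with a per-generation decay
  ``psi`` (default 0.5), and the similarity of two terms is the summed
  contribution over their shared ancestor closure divided by the sum of
  their total semantic values;
* **Gaussian interaction profile (GIP) kernel** similarity,
  ``exp(-rho * ||K_i - K_j||^2)`` between rows (circRNAs) or columns
  (diseases) of the binary association matrix, with bandwidth ``rho``
  the reciprocal mean squared profile norm.

Because sequence and semantic similarity are sparse, each is fused with
its GIP counterpart entrywise: the primary value where nonzero, the GIP
value elsewhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import edlib
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .io import DiseaseDAG, SequenceRecord

DEFAULT_PSI = 0.5  # per-generation semantic contribution decay


@dataclass
class SimilarityMatrix:
    """A square symmetric score matrix in [0, 1] over a fixed id order."""

    values: np.ndarray
    ids: list[str]
    kind: str  # sequence | semantic | gip | fused

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("values must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), ids=[str(c) for c in df.columns], kind=kind)


def levenshtein(s1: str, s2: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute)."""
    if not s1 or not s2:
        return max(len(s1), len(s2))
    return edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]


def sequence_similarity(s1: str, s2: str) -> float:
    """Sequence similarity ``1 - LevDis / (len1 + len2)`` in [0, 1]."""
    total = len(s1) + len(s2)
    if total == 0:
        raise ValueError("similarity of two empty sequences is undefined (0/0)")
    return 1.0 - levenshtein(s1, s2) / total


def sequence_similarity_matrix(records: list[SequenceRecord]) -> SimilarityMatrix:
    """All-pairs sequence similarity; each unordered pair computed once."""
    if not records:
        raise ValueError("need at least one sequence record")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(records)
    S = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        S[i, j] = S[j, i] = sequence_similarity(records[i].seq, records[j].seq)
    return SimilarityMatrix(values=S, ids=ids, kind="sequence")


def contribution_map(dag: DiseaseDAG, d: str, psi: float = DEFAULT_PSI) -> dict[str, float]:
    """Semantic contribution of each term in the ancestor closure of ``d``.

    The focal disease contributes 1 to itself; a proper ancestor ``t``
    contributes ``max(psi * D(t'))`` over its children ``t'`` inside the
    closure. Contributions therefore decay geometrically along
    child->ancestor chains.
    """
    if d not in dag.terms:
        raise KeyError(d)
    closure = {d} | dag.ancestors(d)
    # induced child->parent subgraph; topological order yields children first
    sub = nx.DiGraph()
    sub.add_nodes_from(closure)
    for t in closure:
        for p in dag.parents.get(t, ()):
            if p in closure:
                sub.add_edge(t, p)
    contrib: dict[str, float] = {}
    for t in nx.topological_sort(sub):
        if t == d:
            contrib[t] = 1.0
        else:
            contrib[t] = max(psi * contrib[c] for c, _ in sub.in_edges(t))
    return contrib


def semantic_similarity(dag: DiseaseDAG, di: str, dj: str, psi: float = DEFAULT_PSI) -> float:
    """Wang semantic similarity between two ontology terms.

    Shared-closure contributions summed from both sides, normalized by the
    two total semantic values; 1 on the diagonal, 0 for terms in disjoint
    components.
    """
    ci = contribution_map(dag, di, psi)
    cj = contribution_map(dag, dj, psi)
    shared = ci.keys() & cj.keys()
    num = sum(ci[t] + cj[t] for t in shared)
    den = sum(ci.values()) + sum(cj.values())
    return num / den


def semantic_similarity_matrix(
    dag: DiseaseDAG, ids: list[str], psi: float = DEFAULT_PSI
) -> SimilarityMatrix:
    maps = {d: contribution_map(dag, d, psi) for d in ids}
    totals = {d: sum(m.values()) for d, m in maps.items()}
    n = len(ids)
    S = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        ci, cj = maps[ids[i]], maps[ids[j]]
        shared = ci.keys() & cj.keys()
        num = sum(ci[t] + cj[t] for t in shared)
        S[i, j] = S[j, i] = num / (totals[ids[i]] + totals[ids[j]])
    return SimilarityMatrix(values=S, ids=ids, kind="semantic")


def gip_bandwidth(A: np.ndarray, axis: str) -> float:
    """Kernel bandwidth rho = 1 / mean squared profile norm.

    ``axis='circ'`` uses rows (circRNA interaction profiles),
    ``axis='disease'`` uses columns.
    """
    A = np.asarray(A, dtype=float)
    if axis == "circ":
        norms = (A**2).sum(axis=1)
    elif axis == "disease":
        norms = (A**2).sum(axis=0)
    else:
        raise ValueError(f"axis must be 'circ' or 'disease', got {axis!r}")
    mean = norms.mean()
    if mean == 0:
        raise ValueError("association matrix has no nonzero entries along axis")
    return 1.0 / mean


def gip_similarity(
    A: np.ndarray, circ_ids: list[str] | None = None, dis_ids: list[str] | None = None
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """GIP kernel similarity matrices for circRNAs (rows) and diseases
    (columns) of a binary association matrix."""
    A = np.asarray(A, dtype=float)
    nc, nd = A.shape
    circ_ids = circ_ids if circ_ids is not None else [f"c{i}" for i in range(nc)]
    dis_ids = dis_ids if dis_ids is not None else [f"d{j}" for j in range(nd)]

    def kernel(profiles: np.ndarray, rho: float) -> np.ndarray:
        if profiles.shape[0] == 1:
            return np.ones((1, 1))
        d2 = squareform(pdist(profiles, metric="sqeuclidean"))
        K = np.exp(-rho * d2)
        np.fill_diagonal(K, 1.0)
        return K

    SC = kernel(A, gip_bandwidth(A, "circ"))
    SD = kernel(A.T, gip_bandwidth(A, "disease"))
    return (
        SimilarityMatrix(values=SC, ids=circ_ids, kind="gip"),
        SimilarityMatrix(values=SD, ids=dis_ids, kind="gip"),
    )


def fuse(primary: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Fused similarity: primary value where nonzero, GIP value elsewhere."""
    if primary.ids != gip.ids:
        raise ValueError("id order mismatch between similarity matrices")
    fused = np.where(primary.values != 0, primary.values, gip.values)
    return SimilarityMatrix(values=fused, ids=list(primary.ids), kind="fused")
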