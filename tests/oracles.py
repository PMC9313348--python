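"""Independent brute-force oracles used to validate the implementation.

Each oracle is written from the mathematical definition in a form that
shares no code path with the package: DP edit distance, path-power
semantic contributions, double-loop kernels, exhaustive pair/threshold
metric enumeration, and a triple-loop graph convolution.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def levenshtein_dp(s1: str, s2: str) -> int:
    """Classic dynamic-programming edit distance with unit costs."""
    prev = list(range(len(s2) + 1))
    for i, a in enumerate(s1, start=1):
        cur = [i]
        for j, b in enumerate(s2, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (a != b)))
        prev = cur
    return prev[-1]


def semantic_similarity_bruteforce(parents: dict[str, set[str]], di: str, dj: str, psi: float) -> float:
    """Wang similarity from the path characterization: the contribution of
    an ancestor t to d equals psi**dist(d, t), the shortest directed
    child->parent path length (max over children chains of psi products)."""
    g = nx.DiGraph()
    g.add_nodes_from(parents)
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(child, p)

    def contrib(d: str) -> dict[str, float]:
        dist = nx.single_source_shortest_path_length(g, d)
        return {t: psi**k for t, k in dist.items()}

    ci, cj = contrib(di), contrib(dj)
    shared = ci.keys() & cj.keys()
    num = sum(ci[t] + cj[t] for t in shared)
    return num / (sum(ci.values()) + sum(cj.values()))


def gip_naive(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double-loop Gaussian interaction profile kernels for rows/columns."""
    A = np.asarray(A, dtype=float)
    nc, nd = A.shape

    def kernel(profiles: np.ndarray) -> np.ndarray:
        n = profiles.shape[0]
        rho = 1.0 / np.mean([np.dot(profiles[i], profiles[i]) for i in range(n)])
        K = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                diff = profiles[i] - profiles[j]
                K[i, j] = np.exp(-rho * np.dot(diff, diff))
        return K

    return kernel(A), kernel(A.T)


def auc_bruteforce(scores, labels) -> float:
    """Exhaustive positive-negative pair enumeration, ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def aupr_bruteforce(scores, labels) -> float:
    """Step-curve area by explicit threshold enumeration (each distinct
    score is a cutoff; predictions are score >= cutoff)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    area = 0.0
    prev_recall = 0.0
    for cut in sorted(set(s), reverse=True):
        pred = s >= cut
        tp = int((pred & y).sum())
        precision = tp / int(pred.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def gcn_naive(M: np.ndarray, H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Triple-loop ReLU(D^-1/2 (M+I) D^-1/2 H W)."""
    n = M.shape[0]
    Mt = np.asarray(M, dtype=float) + np.eye(n)
    deg = Mt.sum(axis=1)
    Ahat = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            Ahat[i, j] = Mt[i, j] / np.sqrt(deg[i] * deg[j])
    out = Ahat @ H @ W
    return np.maximum(out, 0.0)


def random_dag(rng: np.random.Generator, n_terms: int) -> dict[str, set[str]]:
    """Random rooted DAG as a child->parent map: term k picks 1-2 parents
    among terms 0..k-1 (term 0 is the root)."""
    names = [f"t{k}" for k in range(n_terms)]
    parents: dict[str, set[str]] = {names[0]: set()}
    for k in range(1, n_terms):
        n_par = int(rng.integers(1, min(k, 2) + 1))
        picks = rng.choice(k, size=n_par, replace=False)
        parents[names[k]] = {names[int(p)] for p in picks}
    return parents
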