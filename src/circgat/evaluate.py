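"""Cross-validation, metrics and candidate ranking.

Fivefold cross-validation over the known associations: positives are
partitioned into five test sets; negatives are drawn uniformly without
replacement from the zero entries, balanced in count within each of
train/test. All leakage-prone quantities (GIP similarity, the graph used
for message passing) are recomputed from the training-fold associations
only. AUC uses the Mann-Whitney midrank form (ties count 1/2); AUPR is the
area under the descending-score precision-recall step curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.stats import rankdata

from .gnn import GatGcnModel, ModelConfig
from .hetgraph import HetGraph, build_hetgraph
from .io import AssociationTable, to_matrix
from .rwr import RWRConfig, rwr
from .similarity import (
    SimilarityMatrix,
    fuse,
    gip_similarity,
    semantic_similarity_matrix,
    sequence_similarity_matrix,
)
from .synthetic import SyntheticDataset

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- folds

@dataclass
class FoldSplit:
    train_pos: list[tuple[int, int]]
    test_pos: list[tuple[int, int]]
    train_neg: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]
    fold_index: int
    seed: int


def make_folds(A: np.ndarray, n_folds: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Partition the positives of ``A`` into ``n_folds`` test sets and draw
    balanced negatives from the zeros, disjointly across roles."""
    A = np.asarray(A)
    positives = [tuple(p) for p in np.argwhere(A != 0)]
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positives, have {len(positives)}")
    zeros = [tuple(p) for p in np.argwhere(A == 0)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    chunks = np.array_split(order, n_folds)
    folds = []
    for f, chunk in enumerate(chunks):
        test_pos = [positives[i] for i in chunk]
        train_pos = [positives[i] for i in order if i not in set(chunk)]
        need = len(train_pos) + len(test_pos)
        if need > len(zeros):
            raise ValueError("not enough zero entries to sample balanced negatives")
        pick = rng.permutation(len(zeros))[:need]
        train_neg = [zeros[i] for i in pick[: len(train_pos)]]
        test_neg = [zeros[i] for i in pick[len(train_pos):]]
        folds.append(
            FoldSplit(
                train_pos=train_pos,
                test_pos=test_pos,
                train_neg=train_neg,
                test_neg=test_neg,
                fold_index=f + 1,
                seed=seed,
            )
        )
    return folds


# -------------------------------------------------------------------- metrics

def auc_score(scores, labels) -> float:
    """Probability a random positive outranks a random negative, ties 1/2
    (the Mann-Whitney U statistic normalized by n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_score requires both classes")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr_score(scores, labels) -> float:
    """Area under the precision-recall step curve swept by descending
    score; tied scores enter as one threshold group."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("aupr_score requires at least one positive")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    # group boundaries where the (descending) score changes
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, len(s) - 1)
    tp = np.cumsum(y)[ends]
    n_pred = ends + 1.0
    precision = tp / n_pred
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def pr_points(scores, labels) -> np.ndarray:
    """(recall, precision) points of the descending-score sweep."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tp = np.cumsum(y)
    n_pred = np.arange(1, len(y) + 1)
    return np.column_stack([tp / max(y.sum(), 1), tp / n_pred])


def roc_points(scores, labels) -> np.ndarray:
    """(fpr, tpr) points of the descending-score sweep."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    return np.column_stack([fp / max((1 - y).sum(), 1), tp / max(y.sum(), 1)])


def threshold_metrics(scores, labels, threshold: float = 0.5) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) at a fixed decision threshold.

    Precision and F1 are reported as 0 (with a warning) when nothing is
    predicted positive.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = s >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    acc = (tp + tn) / max(len(y), 1)
    if tp + fp == 0:
        logger.warning("threshold_metrics: no positive predictions at t=%.3g", threshold)
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return acc, pre, rec, f1


@dataclass
class FoldMetrics:
    auc: float
    aupr: float
    acc: float
    pre: float
    rec: float
    f1: float

    @classmethod
    def from_scores(cls, scores, labels, threshold: float = 0.5) -> "FoldMetrics":
        acc, pre, rec, f1 = threshold_metrics(scores, labels, threshold)
        return cls(
            auc=auc_score(scores, labels),
            aupr=aupr_score(scores, labels),
            acc=acc, pre=pre, rec=rec, f1=f1,
        )

    @classmethod
    def mean(cls, items: list["FoldMetrics"]) -> "FoldMetrics":
        return cls(**{
            f.name: float(np.mean([getattr(m, f.name) for m in items]))
            for f in fields(cls)
        })


# ------------------------------------------------------------------ ablation

@dataclass(frozen=True)
class AblationConfig:
    use_rwr: bool = True
    use_gat: bool = True
    use_gcn: bool = True
    use_fc: bool = True

    def __post_init__(self) -> None:
        if not (self.use_gat or self.use_gcn):
            raise ValueError("at least one of use_gat/use_gcn must be True")


# -------------------------------------------------------------- CV pipeline

def _node_pairs(pairs: list[tuple[int, int]], nc: int) -> np.ndarray:
    """Map (circ_index, dis_index) matrix pairs to graph node-index pairs."""
    arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    return np.column_stack([arr[:, 0], arr[:, 1] + nc])


def base_similarities(dataset: SyntheticDataset) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Sequence and semantic similarity in association-table entity order
    (association-independent, so computed once per dataset)."""
    by_id = {r.id: r for r in dataset.sequences}
    records = [by_id[c] for c in dataset.assoc.circ_ids]
    seq = sequence_similarity_matrix(records)
    sem = semantic_similarity_matrix(dataset.dag, dataset.assoc.dis_ids)
    return seq, sem


def build_fold_graph(
    A_train: np.ndarray,
    seq_sim: SimilarityMatrix,
    sem_sim: SimilarityMatrix,
    mu: float = 0.6,
    use_rwr: bool = True,
    rwr_cfg: RWRConfig = RWRConfig(),
) -> HetGraph:
    """Similarity fusion + optional RWR + heterogeneous-graph assembly,
    computed from training-fold associations only."""
    sc_gip, sd_gip = gip_similarity(A_train, seq_sim.ids, sem_sim.ids)
    sc_fus = fuse(seq_sim, sc_gip)
    sd_fus = fuse(sem_sim, sd_gip)
    if use_rwr:
        SC = rwr(sc_fus.values, rwr_cfg)
        SD = rwr(sd_fus.values, rwr_cfg)
    else:
        SC, SD = sc_fus.values, sd_fus.values
    return build_hetgraph(SC, SD, A_train, mu)


def run_cv(
    dataset: SyntheticDataset,
    model_cfg: ModelConfig = ModelConfig(),
    ablation: AblationConfig = AblationConfig(),
    rwr_cfg: RWRConfig = RWRConfig(),
    mu: float = 0.6,
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    threshold: float = 0.5,
    return_scores: bool = False,
):
    """Fivefold cross-validation of the full pipeline.

    Per fold: test positives removed from the association matrix, GIP
    recomputed from the training fold, similarities fused, optionally
    propagated by RWR, the masked heterogeneous graph assembled, the model
    trained on balanced train pairs and evaluated on balanced test pairs.
    Negatives are resampled independently per repeat. Returns the per-fold
    metrics (all repeats) and their mean.
    """
    A = to_matrix(dataset.assoc)
    nc = dataset.assoc.n_circ
    seq_sim, sem_sim = base_similarities(dataset)
    per_fold: list[FoldMetrics] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for rep in range(n_repeats):
        rep_rng = np.random.default_rng([seed, rep])
        fold_seed = int(rep_rng.integers(2**31))
        for fold in make_folds(A, n_folds, fold_seed):
            A_train = A.copy()
            for i, j in fold.test_pos:
                A_train[i, j] = 0
            G = build_fold_graph(
                A_train, seq_sim, sem_sim, mu, ablation.use_rwr, rwr_cfg
            )
            cfg = replace(model_cfg, seed=int(rep_rng.integers(2**31)))
            model = GatGcnModel(
                n_input=G.n_nodes,
                cfg=cfg,
                use_gat=ablation.use_gat,
                use_gcn=ablation.use_gcn,
                use_fc=ablation.use_fc,
            )
            model.fit(
                G.M, G.X,
                _node_pairs(fold.train_pos, nc),
                _node_pairs(fold.train_neg, nc),
            )
            test_pairs = fold.test_pos + fold.test_neg
            scores = model.predict(G.M, G.X, _node_pairs(test_pairs, nc))
            labels = np.concatenate([np.ones(len(fold.test_pos)), np.zeros(len(fold.test_neg))])
            per_fold.append(FoldMetrics.from_scores(scores, labels, threshold))
            all_scores.append(scores)
            all_labels.append(labels)
    mean = FoldMetrics.mean(per_fold)
    if return_scores:
        return per_fold, mean, (np.concatenate(all_scores), np.concatenate(all_labels))
    return per_fold, mean


# -------------------------------------------------------------------- ranking

@dataclass
class RankedList:
    disease: str
    candidates: list[tuple[str, float]]  # (circRNA id, score), descending
    k: int


def rank_candidates(
    model: GatGcnModel,
    G: HetGraph,
    assoc: AssociationTable,
    disease: str,
    k: int = 10,
    known_pairs: set[tuple[str, str]] | None = None,
) -> RankedList:
    """Top-k candidate circRNAs for one disease, excluding associations the
    model was trained on; ties broken by circRNA id for determinism."""
    if disease not in assoc.dis_ids:
        raise KeyError(f"unknown disease {disease!r}")
    known = known_pairs if known_pairs is not None else set(assoc.pairs)
    j = assoc.dis_ids.index(disease)
    cand = [i for i, c in enumerate(assoc.circ_ids) if (c, disease) not in known]
    pairs = np.column_stack([cand, np.full(len(cand), G.nc + j)])
    scores = model.predict(G.M, G.X, pairs)
    ranked = sorted(
        zip((assoc.circ_ids[i] for i in cand), scores),
        key=lambda t: (-t[1], t[0]),
    )
    return RankedList(disease=disease, candidates=[(c, float(s)) for c, s in ranked[:k]], k=k)


def case_study(
    dataset: SyntheticDataset,
    disease: str,
    k: int = 10,
    model_cfg: ModelConfig = ModelConfig(),
    ablation: AblationConfig = AblationConfig(),
    rwr_cfg: RWRConfig = RWRConfig(),
    mu: float = 0.6,
    seed: int = 0,
) -> RankedList:
    """Leave-one-disease-out ranking experiment: every known association of
    the target disease is set to unknown, the pipeline is rebuilt and
    trained on the remaining data, and all of the disease's circRNAs are
    ranked by predicted score."""
    if disease not in dataset.assoc.dis_ids:
        raise KeyError(f"unknown disease {disease!r}")
    A = to_matrix(dataset.assoc)
    nc = dataset.assoc.n_circ
    j = dataset.assoc.dis_ids.index(disease)
    A_train = A.copy()
    A_train[:, j] = 0
    seq_sim, sem_sim = base_similarities(dataset)
    G = build_fold_graph(A_train, seq_sim, sem_sim, mu, ablation.use_rwr, rwr_cfg)
    rng = np.random.default_rng(seed)
    pos = [tuple(p) for p in np.argwhere(A_train != 0)]
    zeros = [tuple(p) for p in np.argwhere(A_train == 0)]
    neg = [zeros[i] for i in rng.permutation(len(zeros))[: len(pos)]]
    cfg = replace(model_cfg, seed=int(rng.integers(2**31)))
    model = GatGcnModel(
        n_input=G.n_nodes, cfg=cfg,
        use_gat=ablation.use_gat, use_gcn=ablation.use_gcn, use_fc=ablation.use_fc,
    )
    model.fit(G.M, G.X, _node_pairs(pos, nc), _node_pairs(neg, nc))
    trained_known = {
        (dataset.assoc.circ_ids[i], dataset.assoc.dis_ids[jj]) for i, jj in pos
    }
    return rank_candidates(model, G, dataset.assoc, disease, k, known_pairs=trained_known)
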