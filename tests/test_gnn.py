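import numpy as np
import pytest

import circgat as cg
from circgat.gnn import GatGcnModel, ModelConfig, build_edge_index, normalized_adjacency

from oracles import gcn_naive


def small_cfg(**kw) -> ModelConfig:
    base = dict(n_heads=2, embed_dim=8, fc_layers=3, lambda_l2=1e-4, seed=0, epochs=5)
    base.update(kw)
    return ModelConfig(**base)


def random_het(rng, nc, nd):
    A = (rng.random((nc, nd)) < 0.4).astype(int)
    A[0, 0] = 1
    SC = rng.random((nc, nc))
    SC = (SC + SC.T) / 2
    np.fill_diagonal(SC, 1)
    SD = rng.random((nd, nd))
    SD = (SD + SD.T) / 2
    np.fill_diagonal(SD, 1)
    return cg.build_hetgraph(SC, SD, A)


class TestGcnLayer:
    def test_edgeless_graph_with_identity_weights_is_identity_map(self):
        n = 4
        M = np.zeros((n, n), dtype=int)
        H = np.abs(np.random.default_rng(0).random((n, n)))
        model = GatGcnModel(n_input=n, cfg=small_cfg(embed_dim=n), use_gat=False)
        model.params["gcn0.W"] = np.eye(n)
        out = model.node_embeddings(M, H)
        np.testing.assert_allclose(out, H)

    def test_two_node_single_edge_hand_computation(self):
        # degrees 2,2 -> normalized adjacency is all 0.5
        M = np.array([[0, 1], [1, 0]])
        np.testing.assert_allclose(normalized_adjacency(M), 0.5)
        model = GatGcnModel(n_input=2, cfg=small_cfg(embed_dim=2), use_gat=False)
        model.params["gcn0.W"] = np.eye(2)
        out = model.node_embeddings(M, np.eye(2))
        np.testing.assert_allclose(out, 0.5)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(2, 21))
            M = rng.random((n, n)) < 0.3
            M = np.triu(M, 1)
            M = (M | M.T).astype(int)
            H = rng.standard_normal((n, n))
            W = rng.standard_normal((n, 6))
            model = GatGcnModel(n_input=n, cfg=small_cfg(embed_dim=6), use_gat=False)
            model.params["gcn0.W"] = W
            out = model.node_embeddings(M, H)
            np.testing.assert_allclose(out, gcn_naive(M, H, W), atol=1e-12)


class TestGatLayer:
    def test_attention_sums_to_one_per_node_and_head(self, toy_graph):
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg())
        _, (edges, _, caches) = model.node_embeddings(toy_graph.M, toy_graph.X, return_cache=True)
        alpha = next(c for kind, _, c in caches if kind == "gat")[3]
        sums = np.add.reduceat(alpha, edges.row_ptr, axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_zero_attention_vectors_give_uniform_weights(self, toy_graph):
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg())
        model.params["gat0.a_src"][:] = 0
        model.params["gat0.a_dst"][:] = 0
        _, (edges, _, caches) = model.node_embeddings(toy_graph.M, toy_graph.X, return_cache=True)
        alpha = next(c for kind, _, c in caches if kind == "gat")[3]
        degrees = np.diff(np.append(edges.row_ptr, len(edges.src)))
        expected = np.broadcast_to(1.0 / degrees[edges.src], alpha.shape)
        np.testing.assert_allclose(alpha, expected, atol=1e-12)

    def test_isolated_node_attends_only_to_itself(self):
        # single circRNA + single disease, no association: each node's
        # neighborhood is its self-loop, output = ReLU(mean_h W_h x_self)
        G = cg.build_hetgraph(np.array([[1.0]]), np.array([[1.0]]), np.zeros((1, 1)))
        model = GatGcnModel(n_input=2, cfg=small_cfg(), use_gcn=False)
        out = model.node_embeddings(G.M, G.X)
        W = model.params["gat0.W"]
        expected = np.maximum((G.X @ W).mean(axis=0), 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_three_node_path_matches_hand_evaluation(self):
        """One head, scalar weights, path d1 - c - d2: evaluate the
        attention formulas by explicit arithmetic."""
        A = np.array([[1, 1]])  # c0 linked to both diseases
        G = cg.build_hetgraph(np.array([[0.8]]), np.array([[0.7, 0.0], [0.0, 0.9]]), A, mu=1.0)
        model = GatGcnModel(n_input=3, cfg=small_cfg(n_heads=1, embed_dim=1), use_gcn=False)
        w = np.array([[0.5], [1.0], [-0.25]])  # (din=3, 1)
        model.params["gat0.W"] = w[None]
        model.params["gat0.a_src"] = np.array([[2.0]])
        model.params["gat0.a_dst"] = np.array([[1.0]])
        out = model.node_embeddings(G.M, G.X)

        x = G.X
        z = x @ w  # scalar feature per node
        def leaky(v):
            return v if v > 0 else 0.2 * v
        # node 0 neighborhood: {0 (self), 1, 2}
        logits = {j: leaky(2.0 * z[0, 0] + 1.0 * z[j, 0]) for j in (0, 1, 2)}
        ex = {j: np.exp(v) for j, v in logits.items()}
        denom = sum(ex.values())
        expected0 = max(sum(ex[j] / denom * z[j, 0] for j in (0, 1, 2)), 0.0)
        assert out[0, 0] == pytest.approx(expected0, abs=1e-12)
        # node 1 neighborhood: {0, 1}
        logits1 = {j: leaky(2.0 * z[1, 0] + 1.0 * z[j, 0]) for j in (0, 1)}
        ex1 = {j: np.exp(v) for j, v in logits1.items()}
        denom1 = sum(ex1.values())
        expected1 = max(sum(ex1[j] / denom1 * z[j, 0] for j in (0, 1)), 0.0)
        assert out[1, 0] == pytest.approx(expected1, abs=1e-12)

    def test_identical_heads_equal_single_head(self, toy_graph):
        multi = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg(n_heads=4))
        single = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg(n_heads=1))
        for name in ("W", "a_src", "a_dst"):
            multi.params[f"gat0.{name}"] = np.repeat(
                single.params[f"gat0.{name}"], 4, axis=0
            )
        multi.params["gcn0.W"] = single.params["gcn0.W"]
        np.testing.assert_allclose(
            multi.node_embeddings(toy_graph.M, toy_graph.X),
            single.node_embeddings(toy_graph.M, toy_graph.X),
            atol=1e-12,
        )

    def test_permutation_equivariance_within_types(self):
        rng = np.random.default_rng(4)
        G = random_het(rng, 5, 4)
        n = G.n_nodes
        model = GatGcnModel(n_input=n, cfg=small_cfg())
        out = model.node_embeddings(G.M, G.X)
        # permute circRNAs and diseases within their own ranges
        perm = np.r_[rng.permutation(5), 5 + rng.permutation(4)]
        P = np.eye(n)[perm]
        M2 = P @ G.M @ P.T
        X2 = P @ G.X @ P.T
        permuted = GatGcnModel(n_input=n, cfg=small_cfg())
        permuted.params = {k: v.copy() for k, v in model.params.items()}
        # feature columns moved with the nodes, so first-layer input rows follow
        permuted.params["gat0.W"] = model.params["gat0.W"][:, perm, :]
        np.testing.assert_allclose(permuted.node_embeddings(M2, X2), P @ out, atol=1e-10)


class TestScoring:
    def test_zero_weights_give_half_probability(self, toy_graph):
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg())
        for k in model.params:
            if k.startswith("fc"):
                model.params[k][:] = 0.0
        scores = model.predict(toy_graph.M, toy_graph.X, [[0, toy_graph.nc]])
        assert scores[0] == pytest.approx(0.5)

    def test_scores_strictly_inside_unit_interval(self, toy_graph):
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg())
        pairs = [[i, toy_graph.nc + j] for i in range(toy_graph.nc) for j in range(toy_graph.nd)]
        s = model.predict(toy_graph.M, toy_graph.X, pairs)
        assert np.all((s > 0) & (s < 1))

    def test_hand_set_predictor_matches_scalar_arithmetic(self):
        """1-dim embeddings, hand-set fully connected weights."""
        G = cg.build_hetgraph(np.array([[1.0]]), np.array([[1.0]]), np.array([[1]]))
        model = GatGcnModel(n_input=2, cfg=small_cfg(n_heads=1, embed_dim=1, fc_layers=2))
        Hn = model.node_embeddings(G.M, G.X)
        model.params["fc0.W"] = np.array([[0.5], [-1.0]])
        model.params["fc0.b"] = np.array([0.25])
        model.params["fc1.W"] = np.array([[2.0]])
        model.params["fc1.b"] = np.array([-0.1])
        s = model.predict(G.M, G.X, [[0, 1]])[0]
        h0, h1 = Hn[0, 0], Hn[1, 0]
        hidden = max(0.5 * h0 - 1.0 * h1 + 0.25, 0.0)
        logit = 2.0 * hidden - 0.1
        assert s == pytest.approx(1 / (1 + np.exp(-logit)), abs=1e-12)


class TestLoss:
    def test_uninformative_scores_give_log_two(self):
        assert cg.bce_loss([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))

    def test_perfect_scores_approach_zero(self):
        assert cg.bce_loss([1 - 1e-9, 1e-9], [1, 0]) < 1e-6

    def test_l2_term_is_additive(self):
        params = [np.array([1.0, 2.0]), np.array([[3.0]])]
        base = cg.bce_loss([0.7, 0.2], [1, 0])
        with_l2 = cg.bce_loss([0.7, 0.2], [1, 0], params=params, lambda_l2=0.1)
        assert with_l2 == pytest.approx(base + 0.05 * (1 + 4 + 9))

    def test_extreme_scores_are_clamped(self):
        assert np.isfinite(cg.bce_loss([1.0, 0.0], [0, 1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cg.bce_loss([0.5], [1, 0])


class TestTraining:
    def pairs_for(self, G):
        rng = np.random.default_rng(0)
        zeros = np.argwhere(G.M[: G.nc, G.nc:] == 0)
        pos = np.argwhere(G.M[: G.nc, G.nc:]).tolist()[: len(zeros)]
        neg = zeros[rng.choice(len(zeros), size=len(pos), replace=False)].tolist()
        to_nodes = lambda ps: np.array([[i, G.nc + j] for i, j in ps])
        return to_nodes(pos), to_nodes(neg)

    def test_gradients_match_finite_differences(self, toy_graph):
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg(embed_dim=5, lambda_l2=1e-3, seed=3))
        pos, neg = self.pairs_for(toy_graph)
        pairs = np.concatenate([pos, neg])
        labels = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        _, grads = model.loss_and_grads(toy_graph.M, toy_graph.X, pairs, labels)
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name, p in model.params.items():
            flat = rng.choice(p.size, size=min(4, p.size), replace=False)
            for pos_idx in flat:
                ij = np.unravel_index(pos_idx, p.shape)
                orig = p[ij]
                p[ij] = orig + eps
                lp, _ = model.loss_and_grads(toy_graph.M, toy_graph.X, pairs, labels)
                p[ij] = orig - eps
                lm, _ = model.loss_and_grads(toy_graph.M, toy_graph.X, pairs, labels)
                p[ij] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[name][ij] == pytest.approx(fd, rel=1e-4, abs=1e-9), name

    def test_loss_decreases_and_same_seed_reproduces(self, toy_graph):
        pos, neg = self.pairs_for(toy_graph)
        runs = []
        for _ in range(2):
            model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg(epochs=30, seed=5))
            model.fit(toy_graph.M, toy_graph.X, pos, neg)
            runs.append(model.loss_history)
        assert runs[0] == runs[1]
        assert runs[0][-1] <= runs[0][0]

    def test_unbalanced_negatives_rejected(self, toy_graph):
        pos, neg = self.pairs_for(toy_graph)
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg())
        with pytest.raises(ValueError):
            model.fit(toy_graph.M, toy_graph.X, pos, neg[:-1])

    def test_divergence_aborts_with_diagnostic(self, toy_graph):
        pos, neg = self.pairs_for(toy_graph)
        model = GatGcnModel(n_input=toy_graph.n_nodes, cfg=small_cfg())
        model.params["fc0.W"][:] = np.inf
        with pytest.raises(RuntimeError, match="diverged"):
            model.fit(toy_graph.M, toy_graph.X, pos, neg)

    def test_requires_some_graph_module(self):
        with pytest.raises(ValueError):
            GatGcnModel(n_input=4, cfg=small_cfg(), use_gat=False, use_gcn=False)
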