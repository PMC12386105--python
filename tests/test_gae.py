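import numpy as np
import pytest

from mircoop.config import RunConfig
from mircoop.coop import build_cooperation_network
from mircoop.gae import (
    GAEParameters,
    _objective_and_grads,
    assign_pseudo_labels,
    build_enhanced_network,
    decode,
    difference_prompt_loss,
    encode,
    functional_consistency_loss,
    gip_similarity,
    init_parameters,
    knowledge_similarity,
    normalized_adjacency,
    reconstruction_loss,
    total_loss,
    train,
)
from mircoop.io import ExpressionDataset, KnowledgeTable


class TestNormalizedAdjacency:
    def test_isolated_node_self_loop(self):
        np.testing.assert_allclose(normalized_adjacency(np.zeros((1, 1))), [[1.0]])

    def test_two_node_edge(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalized_adjacency(A), [[0.5, 0.5], [0.5, 0.5]])

    def test_symmetric_output(self):
        rng = np.random.default_rng(0)
        A = (rng.random((8, 8)) < 0.3).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        out = normalized_adjacency(A)
        np.testing.assert_allclose(out, out.T)
        # spectral norm of the symmetric normalization is at most 1
        assert np.max(np.abs(np.linalg.eigvalsh(out))) <= 1 + 1e-12


class TestEncoderDecoder:
    def test_hand_example(self):
        """2-node single-edge graph, X=[[2],[0]], W0=W1=[[1]] gives Z=[[1],[1]]."""
        A_hat = normalized_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        params = GAEParameters(W0=np.array([[1.0]]), W1=np.array([[1.0]]), D_L=np.eye(1))
        Z = encode(A_hat, np.array([[2.0], [0.0]]), params)
        np.testing.assert_allclose(Z, [[1.0], [1.0]])

    def test_zero_input_zero_output(self):
        A_hat = normalized_adjacency(np.zeros((3, 3)))
        params = GAEParameters(W0=np.ones((2, 4)), W1=np.ones((4, 2)), D_L=np.eye(2))
        np.testing.assert_allclose(encode(A_hat, np.zeros((3, 2)), params), np.zeros((3, 2)))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        m = 6
        A = np.triu((rng.random((m, m)) < 0.5).astype(float), 1)
        A = A + A.T
        X = rng.normal(size=(m, 4))
        params = GAEParameters(W0=rng.normal(size=(4, 3)), W1=rng.normal(size=(3, 2)), D_L=np.eye(2))
        perm = rng.permutation(m)
        Z = encode(normalized_adjacency(A), X, params)
        Zp = encode(normalized_adjacency(A[np.ix_(perm, perm)]), X[perm], params)
        np.testing.assert_allclose(Zp, Z[perm], atol=1e-12)

    def test_decode_values(self):
        np.testing.assert_allclose(decode(np.zeros((3, 2))), np.full((3, 3), 0.5))
        Z = np.array([[1.0], [1.0]])
        np.testing.assert_allclose(decode(Z), np.full((2, 2), 1 / (1 + np.exp(-1.0))))
        rng = np.random.default_rng(2)
        A_rec = decode(rng.normal(size=(5, 3)))
        np.testing.assert_allclose(A_rec, A_rec.T)


class TestReconstructionLoss:
    def test_perfect_reconstruction_zero(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert reconstruction_loss(A, A) == 0.0

    def test_half_everywhere(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert reconstruction_loss(A, np.full((2, 2), 0.5)) == pytest.approx(0.25)

    def test_unit_latent_example(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = 1 / (1 + np.exp(-1.0))
        expected = (2 * s**2 + 2 * (1 - s) ** 2) / 4
        assert reconstruction_loss(A, decode(np.array([[1.0], [1.0]]))) == pytest.approx(expected)
        assert expected == pytest.approx(0.3034, abs=1e-4)


class TestGIP:
    def test_orthogonal_unit_profiles(self):
        S = gip_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert S[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_identical_rows_similarity_one(self):
        S = gip_similarity(np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 1.0]]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_kernel_properties(self):
        rng = np.random.default_rng(3)
        S = gip_similarity(rng.normal(size=(7, 4)))
        np.testing.assert_allclose(S, S.T)
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert np.all(S > 0) and np.all(S <= 1)

    def test_all_zero_rows_error(self):
        with pytest.raises(ValueError, match="zero"):
            gip_similarity(np.zeros((3, 2)))

    def test_empty_empty_pairs_zeroed_in_training_target(self):
        assoc = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        GS = knowledge_similarity(assoc)
        assert GS[1, 2] == 0.0 and GS[2, 1] == 0.0
        assert GS[1, 1] == 1.0 and GS[2, 2] == 1.0
        assert GS[0, 1] > 0  # empty-vs-nonempty keeps the kernel value


class TestFunctionalConsistency:
    def test_identity_zero(self):
        S = np.eye(3)
        assert functional_consistency_loss(S, S) == 0.0

    def test_hand_example(self):
        e2 = np.exp(-2.0)
        GS = np.array([[1.0, e2], [e2, 1.0]])
        loss = functional_consistency_loss(GS, np.ones((2, 2)))
        assert loss == pytest.approx(2 * (1 - e2) ** 2)
        assert loss == pytest.approx(1.4953, abs=1e-4)

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError):
            functional_consistency_loss(np.eye(2), np.eye(3))


class TestPseudoLabels:
    def test_differential_feature_flagged(self, tiny_data):
        labels = assign_pseudo_labels(tiny_data)
        assert labels[0]  # f1 was shifted by 4 sd

    def test_textbook_feature(self):
        data = ExpressionDataset(
            feature_ids=["f0"],
            sample_ids=[f"s{i}" for i in range(6)],
            values=np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]]),
            labels=np.array([1, 1, 1, 0, 0, 0]),
        )
        assert assign_pseudo_labels(data)[0]  # p = 0.0213 < 0.05

    def test_totality(self, benchmark):
        data, _, _ = benchmark
        labels = assign_pseudo_labels(data)
        assert labels.shape == (data.n_features,)
        assert labels.dtype == bool


def naive_difference_prompt(U, y, tau):
    """Double-loop evaluation of the supervised-contrastive objective."""
    m = len(U)
    total = 0.0
    for i in range(m):
        B = [b for b in range(m) if b != i and y[b] == y[i]]
        if not B:
            continue
        A = [a for a in range(m) if a != i]
        denom = sum(np.exp(U[i] @ U[a] / tau) for a in A)
        total += -(1 / len(B)) * sum(np.log(np.exp(U[i] @ U[b] / tau) / denom) for b in B)
    return total


class TestDifferencePrompt:
    def test_all_identical_outputs(self):
        """Three identical vectors, one class: every softmax term is 1/2."""
        Z = np.ones((3, 2))
        D_L = np.eye(2)
        y = np.array([True, True, True])
        loss = difference_prompt_loss(Z, y, D_L, tau=1.0)
        assert loss == pytest.approx(3 * np.log(2.0))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(5, 3))
        D_L = rng.normal(size=(3, 2))
        y = np.array([True, True, False, False, True])
        for normalize in (True, False):
            V = Z @ D_L
            U = V / np.linalg.norm(V, axis=1, keepdims=True) if normalize else V
            expected = naive_difference_prompt(U, y, 0.1)
            got = difference_prompt_loss(Z, y, D_L, tau=0.1, normalize=normalize)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_singleton_class_skipped(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(4, 2))
        D_L = np.eye(2)
        y = np.array([True, True, True, False])  # the False node has no peer
        loss = difference_prompt_loss(Z, y, D_L, tau=0.5)
        V = Z @ D_L
        U = V / np.linalg.norm(V, axis=1, keepdims=True)
        assert loss == pytest.approx(naive_difference_prompt(U, y, 0.5), abs=1e-9)


class TestTotalLoss:
    def test_zero_weights_reduce_to_reconstruction(self):
        assert total_loss((0.7, 5.0, 9.0), 0.0, 0.0) == 0.7

    def test_default_weights_example(self):
        got = total_loss((0.3034, 1.4953, 2.0794), 0.1, 1e-7)
        assert got == pytest.approx(0.45293, abs=1e-4)

    def test_ablation_flags_drop_terms(self):
        assert total_loss((0.5, 2.0, 3.0), 0.1, 0.5, use_knowledge=False) == pytest.approx(0.5 + 1.5)
        assert total_loss((0.5, 2.0, 3.0), 0.1, 0.5, use_difference_prompt=False) == pytest.approx(0.7)

    def test_negative_weight_error(self):
        with pytest.raises(ValueError):
            total_loss((1.0, 1.0, 1.0), -0.1, 0.0)


def finite_difference_grad(f, M, h=1e-6):
    g = np.zeros_like(M)
    it = np.nditer(M, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = M[idx]
        M[idx] = orig + h
        fp = f()
        M[idx] = orig - h
        fm = f()
        M[idx] = orig
        g[idx] = (fp - fm) / (2 * h)
    return g


class TestGradients:
    def test_analytic_vs_central_differences(self):
        """All parameter blocks of the total objective on a 10-node instance."""
        rng = np.random.default_rng(6)
        m = 10
        A = np.triu((rng.random((m, m)) < 0.4).astype(float), 1)
        A = A + A.T
        A_hat = normalized_adjacency(A)
        X = rng.normal(size=(m, 5))
        GS = gip_similarity((rng.random((m, 3)) < 0.5).astype(float) + 0.0 + np.eye(m, 3) * 0)
        pseudo = rng.random(m) < 0.5
        config = RunConfig(lambda1=0.1, lambda2=0.5, tau=0.1, hidden_dims=(4, 3), discriminator_dim=2)
        params = init_parameters(5, (4, 3), 2, seed=1)
        iu, ju = np.triu_indices(m, 1)
        keep = rng.random(len(iu)) < 0.6
        entries = (iu[keep], ju[keep])

        def objective():
            losses, _ = _objective_and_grads(params, A_hat, X, A, GS, pseudo, config, entries)
            return losses["L_total"]

        _, grads = _objective_and_grads(params, A_hat, X, A, GS, pseudo, config, entries)
        for block, M in (("W0", params.W0), ("W1", params.W1), ("D_L", params.D_L)):
            fd = finite_difference_grad(objective, M)
            rel = np.linalg.norm(grads[block] - fd) / max(np.linalg.norm(fd), 1e-12)
            assert rel < 1e-4, f"gradient mismatch in {block}: rel={rel}"

    def test_gradients_without_optional_terms(self):
        """Reconstruction-only gradients (both ablations off) also check out."""
        rng = np.random.default_rng(7)
        m = 6
        A = np.triu((rng.random((m, m)) < 0.5).astype(float), 1)
        A = A + A.T
        A_hat = normalized_adjacency(A)
        X = rng.normal(size=(m, 4))
        config = RunConfig(use_knowledge=False, use_difference_prompt=False,
                           hidden_dims=(3, 2), discriminator_dim=2)
        params = init_parameters(4, (3, 2), 2, seed=2)

        def objective():
            losses, _ = _objective_and_grads(params, A_hat, X, A, None, None, config, None)
            return losses["L_total"]

        _, grads = _objective_and_grads(params, A_hat, X, A, None, None, config, None)
        for block, M in (("W0", params.W0), ("W1", params.W1)):
            fd = finite_difference_grad(objective, M)
            rel = np.linalg.norm(grads[block] - fd) / max(np.linalg.norm(fd), 1e-12)
            assert rel < 1e-4


class TestTraining:
    def _net(self, data, knowledge, config):
        return build_cooperation_network(data, knowledge, config)

    def test_zero_epochs_returns_initial_encoding(self, tiny_data, tiny_knowledge, fast_config):
        cfg = fast_config.replace(epochs=0)
        net = self._net(tiny_data, tiny_knowledge, cfg)
        params, latent, trace = train(net, tiny_knowledge, tiny_data, cfg)
        init = init_parameters(net.attributes.shape[1], cfg.hidden_dims, cfg.discriminator_dim, cfg.seed)
        np.testing.assert_array_equal(params.W0, init.W0)
        A_hat = normalized_adjacency((net.graph.weights > 0).astype(float))
        np.testing.assert_allclose(latent.Z, encode(A_hat, net.attributes, params))
        assert len(trace.L_total) == 0

    def test_loss_decreases_on_benchmark_subset(self, benchmark):
        data, knowledge, _ = benchmark
        keep = list(range(0, 60))
        sub = ExpressionDataset(
            feature_ids=[data.feature_ids[i] for i in keep],
            sample_ids=list(data.sample_ids),
            values=data.values[:, keep],
            labels=data.labels,
        )
        ksub = KnowledgeTable(
            feature_ids=sub.feature_ids,
            disease_ids=knowledge.disease_ids,
            assoc=knowledge.assoc[keep],
        )
        cfg = RunConfig(seed=0, epochs=200)
        net = build_cooperation_network(sub, ksub, cfg)
        _, _, trace = train(net, ksub, sub, cfg)
        assert trace.L_total[-1] < trace.L_total[0]

    def test_same_seed_identical_trace(self, tiny_data, tiny_knowledge, fast_config):
        net = self._net(tiny_data, tiny_knowledge, fast_config)
        _, z1, t1 = train(net, tiny_knowledge, tiny_data, fast_config)
        _, z2, t2 = train(net, tiny_knowledge, tiny_data, fast_config)
        np.testing.assert_array_equal(t1.L_total, t2.L_total)
        np.testing.assert_array_equal(z1.Z, z2.Z)


class TestEnhancedNetwork:
    def test_zero_dot_product_kept_at_default_theta(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])  # dot = 0 -> weight 0.5
        g = build_enhanced_network(Z, ["a", "b"], theta=0.5)
        assert g.weights[0, 1] == pytest.approx(0.5)

    def test_unit_latent_edge_weight(self):
        g = build_enhanced_network(np.array([[1.0], [1.0]]), ["a", "b"])
        assert g.weights[0, 1] == pytest.approx(1 / (1 + np.exp(-1.0)))

    def test_symmetric_weights_in_unit_interval(self):
        rng = np.random.default_rng(8)
        g = build_enhanced_network(rng.normal(size=(6, 3)), [f"n{i}" for i in range(6)], theta=0.0)
        W = g.weights
        np.testing.assert_allclose(W, W.T)
        off = W[~np.eye(6, dtype=bool)]
        assert np.all((off > 0) & (off < 1))

    def test_restriction_never_adds_edges(self):
        from mircoop.io import WeightedGraph

        rng = np.random.default_rng(9)
        Z = rng.normal(size=(5, 2))
        A = np.zeros((5, 5))
        A[0, 1] = A[1, 0] = 1.0
        base = WeightedGraph(node_ids=[f"n{i}" for i in range(5)], weights=A)
        g = build_enhanced_network(Z, base.node_ids, theta=0.0, restrict_to=base)
        assert set(zip(*np.nonzero(g.weights))) <= {(0, 1), (1, 0)}
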