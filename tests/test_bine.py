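import warnings

import numpy as np
import pytest

from mirdrug.bine import (
    BineConfig,
    NodeEmbeddingTable,
    WalkCorpus,
    context_pairs,
    explicit_joint_probability,
    explicit_loss,
    generate_walks,
    hits_centrality,
    load_word2vec,
    local_proximity,
    sample_negatives,
    save_word2vec,
    sga_step_explicit,
    sga_step_implicit,
    sigmoid,
    train_bine,
)
from mirdrug.graph import BipartiteGraph, HomogeneousWeights, cohits_projection

from conftest import random_bipartite

SIG1 = 1.0 / (1.0 + np.exp(-1.0))  # sigma(1) = 0.7310585786...


class TestExplicitProbability:
    def test_single_edge(self):
        g = BipartiteGraph(["d"], ["m"], {(0, 0): 1.0})
        assert explicit_joint_probability(g, 0, 0) == 1.0

    def test_two_unit_edges(self, identity_graph):
        assert explicit_joint_probability(identity_graph, 0, 0) == 0.5

    def test_hand_normalization(self):
        g = BipartiteGraph(["d1", "d2"], ["m1", "m2"], {(0, 0): 2.0, (0, 1): 1.0, (1, 1): 1.0})
        assert explicit_joint_probability(g, 0, 0) == pytest.approx(0.5)
        assert explicit_joint_probability(g, 0, 1) == pytest.approx(0.25)
        assert explicit_joint_probability(g, 1, 1) == pytest.approx(0.25)

    def test_non_edge_errors(self, identity_graph):
        with pytest.raises(KeyError):
            explicit_joint_probability(identity_graph, 0, 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        g = random_bipartite(rng, 7, 9, weighted=True)
        total = sum(explicit_joint_probability(g, i, j) for i, j in g.edges)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestLocalProximity:
    def test_zero_vectors(self):
        assert local_proximity(np.zeros(4), np.zeros(4)) == 0.5

    def test_scalar_values(self):
        assert local_proximity([2.0, 0.0], [2.0, 0.0]) == pytest.approx(0.98201379, abs=1e-6)
        assert local_proximity([1.0, 0.0], [-1.0, 0.0]) == pytest.approx(0.26894142, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            local_proximity([1.0], [1.0, 2.0])


class TestExplicitLoss:
    def test_limit_single_edge(self):
        g = BipartiteGraph(["d"], ["m"], {(0, 0): 1.0})
        big = NodeEmbeddingTable(np.full((1, 2), 3.0), np.full((1, 2), 3.0),
                                 np.zeros((1, 2)), np.zeros((1, 2)))
        assert explicit_loss(g, big) < 1e-7  # P_hat -> 1 drives KL -> 0

    def test_closed_form_at_half(self, toy_graph):
        emb = NodeEmbeddingTable(np.zeros((2, 4)), np.zeros((2, 4)),
                                 np.zeros((2, 4)), np.zeros((2, 4)))
        ps = [explicit_joint_probability(toy_graph, i, j) for i, j in toy_graph.edges]
        expected = sum(p * np.log(2 * p) for p in ps)
        assert explicit_loss(toy_graph, emb) == pytest.approx(expected, abs=1e-12)

    def test_training_decreases_loss(self):
        rng = np.random.default_rng(0)
        g = random_bipartite(rng, 4, 4, density=0.5)
        cfg = BineConfig(dim=8, epochs=30, seed=1, min_walks_per_node=2)
        emb0 = NodeEmbeddingTable.init_random(4, 4, 8, np.random.default_rng(1))
        trained = train_bine(g, cfg)
        assert explicit_loss(g, trained) < explicit_loss(g, emb0)


class TestHitsCentrality:
    def test_complete_graph_uniform(self):
        mat = np.ones((3, 3)) - np.eye(3)
        c = hits_centrality(HomogeneousWeights("drug", mat))
        assert np.allclose(c, 1 / 3)

    def test_star_center_dominates(self):
        mat = np.zeros((4, 4))
        mat[0, 1:] = mat[1:, 0] = 1.0
        c = hits_centrality(HomogeneousWeights("drug", mat))
        assert all(c[0] > c[k] for k in (1, 2, 3))

    def test_matches_eigenvector_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.random((5, 5))
        mat = a + a.T
        c = hits_centrality(HomogeneousWeights("drug", mat), tol=1e-15, max_iter=20000)
        w, v = np.linalg.eigh(mat)
        dom = np.abs(v[:, np.argmax(w)])
        assert np.allclose(c, dom / dom.sum(), atol=1e-8)

    def test_zero_matrix_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            c = hits_centrality(HomogeneousWeights("drug", np.zeros((4, 4))))
        assert np.allclose(c, 0.25)


class TestGenerateWalks:
    def make_proj(self, mat):
        return HomogeneousWeights("drug", np.asarray(mat, dtype=float))

    def test_stop_prob_one_gives_length_one(self):
        h = self.make_proj(np.ones((4, 4)))
        cfg = BineConfig(stop_prob=1.0)
        corpus = generate_walks(h, np.full(4, 0.25), cfg, np.random.default_rng(0))
        assert corpus.sequences and all(len(s) == 1 for s in corpus.sequences)

    def test_isolated_node_walks_length_one(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 1.0
        cfg = BineConfig(stop_prob=0.1)
        corpus = generate_walks(self.make_proj(mat), np.full(3, 1 / 3), cfg, np.random.default_rng(0))
        starts2 = [s for s in corpus.sequences if s[0] == 2]
        assert starts2 and all(len(s) == 1 for s in starts2)

    def test_weighted_step_frequencies(self):
        # node 0 has neighbors 1 (weight 3) and 2 (weight 1)
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = 3.0
        mat[0, 2] = mat[2, 0] = 1.0
        h = self.make_proj(mat)
        cfg = BineConfig(stop_prob=0.5, max_walks_per_node=1, min_walks_per_node=1)
        rng = np.random.default_rng(123)
        hits = {1: 0, 2: 0}
        for _ in range(10000):
            corpus = generate_walks(h, np.array([1.0, 0.0, 0.0]), cfg, rng)
            seq = corpus.sequences[0]
            if len(seq) > 1:
                hits[seq[1]] += 1
        frac = hits[1] / (hits[1] + hits[2])
        assert abs(frac - 0.75) < 0.02

    def test_walk_counts_clamped(self):
        mat = np.ones((5, 5))
        cfg = BineConfig(max_walks_per_node=10, min_walks_per_node=2, stop_prob=1.0)
        cent = np.array([0.8, 0.2, 0.0, 0.0, 0.0])
        corpus = generate_walks(self.make_proj(mat), cent, cfg, np.random.default_rng(0))
        starts = np.bincount([s[0] for s in corpus.sequences], minlength=5)
        # clamp(round(10*c), 2, 10)
        assert list(starts) == [8, 2, 2, 2, 2]

    def test_walk_validity_off_diagonal_neighbors(self, toy_graph):
        h = cohits_projection(toy_graph, "mirna")
        cfg = BineConfig(stop_prob=0.2, min_walks_per_node=4)
        cent = hits_centrality(h)
        corpus = generate_walks(h, cent, cfg, np.random.default_rng(1))
        mat = h.dense()
        for seq in corpus.sequences:
            for a, b in zip(seq, seq[1:]):
                assert a != b and mat[a, b] > 0


class TestContextPairs:
    def test_window_one(self):
        corpus = WalkCorpus("drug", [[0, 1, 2]])
        c, z = context_pairs(corpus, 1)
        assert sorted(zip(c, z)) == [(0, 1), (1, 0), (1, 2), (2, 1)]

    def test_singleton_sequence(self):
        c, z = context_pairs(WalkCorpus("drug", [[5]]), 3)
        assert len(c) == 0

    def test_window_two_count(self):
        c, _ = context_pairs(WalkCorpus("drug", [[0, 1, 2, 3]]), 2)
        assert len(c) == 10

    @pytest.mark.parametrize("window", [1, 2, 4])
    def test_bruteforce_enumeration(self, window):
        rng = np.random.default_rng(window)
        seq = list(rng.integers(0, 9, size=13))
        expected = [
            (seq[t], seq[u])
            for t in range(len(seq))
            for u in range(len(seq))
            if u != t and abs(u - t) <= window
        ]
        c, z = context_pairs(WalkCorpus("drug", [seq]), window)
        assert sorted(zip(c, z)) == sorted(expected)


class TestSgaSteps:
    def cfg(self):
        return BineConfig(dim=2, lr=0.1, alpha=1.0, beta=1.0, gamma=1.0)

    def table(self, d, m, th=None, vh=None):
        z = np.zeros((1, 2))
        return NodeEmbeddingTable(np.array([d]), np.array([m]),
                                  np.array([th]) if th is not None else z.copy(),
                                  np.array([vh]) if vh is not None else z.copy())

    def test_explicit_zero_fixed_point(self):
        g = BipartiteGraph(["d"], ["m"], {(0, 0): 1.0})
        emb = self.table([0.0, 0.0], [0.0, 0.0])
        sga_step_explicit(emb, g, 0, 0, self.cfg())
        assert not emb.drug_vecs.any() and not emb.mirna_vecs.any()

    def test_explicit_hand_value(self):
        g = BipartiteGraph(["d"], ["m"], {(0, 0): 1.0})
        emb = self.table([1.0, 0.0], [1.0, 0.0])
        sga_step_explicit(emb, g, 0, 0, self.cfg())
        assert emb.drug_vecs[0] == pytest.approx([1 + 0.1 * (1 - SIG1), 0.0], abs=1e-9)
        # miRNA row updated with the PRE-update drug vector
        assert emb.mirna_vecs[0] == pytest.approx([1 + 0.1 * (1 - SIG1), 0.0], abs=1e-9)

    def test_explicit_monotone_saturation(self):
        g = BipartiteGraph(["d"], ["m"], {(0, 0): 1.0})
        emb = self.table([0.5, 0.1], [0.3, -0.2])
        prev = sigmoid(emb.drug_vecs[0] @ emb.mirna_vecs[0])
        for _ in range(50):
            sga_step_explicit(emb, g, 0, 0, self.cfg())
            cur = sigmoid(emb.drug_vecs[0] @ emb.mirna_vecs[0])
            assert cur > prev
            prev = cur

    def test_implicit_zero_fixed_point(self):
        emb = self.table([0.0, 0.0], [0.0, 0.0])
        sga_step_implicit(emb, 0, [(0, True)], "drug", self.cfg())
        assert not emb.drug_vecs.any() and not emb.drug_ctx.any()

    def test_implicit_positive_hand_value(self):
        emb = self.table([1.0, 0.0], [0.0, 0.0], th=[1.0, 0.0])
        sga_step_implicit(emb, 0, [(0, True)], "drug", self.cfg())
        assert emb.drug_vecs[0] == pytest.approx([1 + 0.1 * (1 - SIG1), 0.0], abs=1e-9)
        assert emb.drug_ctx[0] == pytest.approx([1 + 0.1 * (1 - SIG1), 0.0], abs=1e-9)

    def test_implicit_negative_hand_value(self):
        emb = self.table([1.0, 0.0], [0.0, 0.0], th=[1.0, 0.0])
        sga_step_implicit(emb, 0, [(0, False)], "drug", self.cfg())
        assert emb.drug_vecs[0] == pytest.approx([1 - 0.1 * SIG1, 0.0], abs=1e-9)


class TestGradientChecks:
    """Each SGA rule must match a finite-difference gradient of its term."""

    def numeric_grad(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        for k in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[k] += eps
            xm[k] -= eps
            g[k] = (f(xp) - f(xm)) / (2 * eps)
        return g

    @pytest.mark.parametrize("seed", range(10))
    def test_explicit_rule_is_gradient_ascent(self, seed):
        rng = np.random.default_rng(seed)
        d, m = rng.normal(size=4), rng.normal(size=4)
        w, lr, gamma = float(rng.uniform(0.5, 2)), 0.05, float(rng.uniform(0.5, 2))
        g = BipartiteGraph(["d"], ["m"], {(0, 0): w})
        cfg = BineConfig(dim=4, lr=lr, gamma=gamma)
        emb = NodeEmbeddingTable(np.array([d]), np.array([m]), np.zeros((1, 4)), np.zeros((1, 4)))
        sga_step_explicit(emb, g, 0, 0, cfg)
        obj_d = lambda x: gamma * w * np.log(sigmoid(x @ m))
        obj_m = lambda x: gamma * w * np.log(sigmoid(d @ x))
        np.testing.assert_allclose(emb.drug_vecs[0] - d, lr * self.numeric_grad(obj_d, d), rtol=1e-5)
        np.testing.assert_allclose(emb.mirna_vecs[0] - m, lr * self.numeric_grad(obj_m, m), rtol=1e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_implicit_rule_is_gradient_ascent(self, seed):
        rng = np.random.default_rng(100 + seed)
        v = rng.normal(size=4)
        th = rng.normal(size=(3, 4))
        lr, alpha = 0.05, float(rng.uniform(0.5, 2))
        cfg = BineConfig(dim=4, lr=lr, alpha=alpha, beta=alpha)
        emb = NodeEmbeddingTable(np.vstack([v, np.zeros((2, 4))]), np.zeros((1, 4)),
                                 th.copy(), np.zeros((1, 4)))
        contexts = [(1, True), (2, False)]
        sga_step_implicit(emb, 0, contexts, "drug", cfg)

        def obj_center(x):
            return alpha * (np.log(sigmoid(x @ th[1])) + np.log(1 - sigmoid(x @ th[2])))

        np.testing.assert_allclose(emb.drug_vecs[0] - v, lr * self.numeric_grad(obj_center, v), rtol=1e-5)
        obj_pos = lambda t: alpha * np.log(sigmoid(v @ t))
        obj_neg = lambda t: alpha * np.log(1 - sigmoid(v @ t))
        np.testing.assert_allclose(emb.drug_ctx[1] - th[1], lr * self.numeric_grad(obj_pos, th[1]), rtol=1e-5)
        np.testing.assert_allclose(emb.drug_ctx[2] - th[2], lr * self.numeric_grad(obj_neg, th[2]), rtol=1e-5)


class TestSampleNegatives:
    def test_pool_of_one(self):
        rng = np.random.default_rng(0)
        negs = sample_negatives(0, [1], [0, 1, 2], ns=5, rng=rng)
        assert negs == [2] * 5

    def test_seeded_determinism(self):
        a = sample_negatives(0, [1], list(range(10)), 6, np.random.default_rng(42))
        b = sample_negatives(0, [1], list(range(10)), 6, np.random.default_rng(42))
        assert a == b

    def test_degree_biased_frequency(self):
        rng = np.random.default_rng(7)
        degrees = np.array([0.0, 8.0, 1.0, 1.0])
        counts = {1: 0, 2: 0, 3: 0}
        draws = 10000
        for k in sample_negatives(0, [], [1, 2, 3], ns=draws, rng=rng,
                                  strategy="unigram", degrees=degrees):
            counts[k] += 1
        expected = 8**0.75 / (8**0.75 + 2.0)
        assert abs(counts[1] / draws - expected) < 0.02

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning):
            negs = sample_negatives(0, [1], [0, 1], 3, np.random.default_rng(0))
        assert negs == []

    def test_lsh_strategy_excludes_center_bucket(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(20, 8))
        negs = sample_negatives(0, [1], list(range(20)), 10, rng,
                                strategy="lsh", embeddings=emb)
        assert len(negs) == 10 and 0 not in negs and 1 not in negs


class TestTrainBine:
    def two_block_graph(self):
        edges = {}
        for b in range(2):
            for i in range(5):
                for j in range(5):
                    edges[(b * 5 + i, b * 5 + j)] = 1.0
        return BipartiteGraph([f"d{i}" for i in range(10)], [f"m{j}" for j in range(10)], edges)

    def test_block_separation(self):
        g = self.two_block_graph()
        emb = train_bine(g, BineConfig(dim=16, epochs=30, seed=2, min_walks_per_node=4))
        V = emb.drug_vecs / np.linalg.norm(emb.drug_vecs, axis=1, keepdims=True)
        C = V @ V.T
        blocks = np.array([0] * 5 + [1] * 5)
        same = blocks[:, None] == blocks[None, :]
        np.fill_diagonal(same, False)
        other = ~same & ~np.eye(10, dtype=bool)
        assert C[same].mean() > C[other].mean()

    def test_default_dimensions(self):
        g = self.two_block_graph()
        emb = train_bine(g, BineConfig(epochs=1, seed=0, min_walks_per_node=1))
        assert emb.drug_vecs.shape == (10, 64)
        assert emb.mirna_vecs.shape == (10, 64)

    def test_edge_score_separation(self):
        g = self.two_block_graph()
        emb = train_bine(g, BineConfig(dim=16, epochs=30, seed=5, min_walks_per_node=4))
        rng = np.random.default_rng(0)
        non = []
        while len(non) < g.n_edges:
            i, j = int(rng.integers(10)), int(rng.integers(10))
            if (i, j) not in g.edges:
                non.append((i, j))
        s_edge = np.mean([sigmoid(emb.drug_vecs[i] @ emb.mirna_vecs[j]) for i, j in g.edges])
        s_non = np.mean([sigmoid(emb.drug_vecs[i] @ emb.mirna_vecs[j]) for i, j in non])
        assert s_edge > s_non

    def test_bitwise_determinism(self):
        g = self.two_block_graph()
        cfg = BineConfig(dim=8, epochs=5, seed=77, min_walks_per_node=2)
        a, b = train_bine(g, cfg), train_bine(g, cfg)
        for attr in ("drug_vecs", "mirna_vecs", "drug_ctx", "mirna_ctx"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_corpus_determinism(self, toy_graph):
        cfg = BineConfig(stop_prob=0.3, min_walks_per_node=4)
        h = cohits_projection(toy_graph, "drug")
        cent = hits_centrality(h)
        c1 = generate_walks(h, cent, cfg, np.random.default_rng(5))
        c2 = generate_walks(h, cent, cfg, np.random.default_rng(5))
        assert c1.sequences == c2.sequences

    def test_isolated_nodes_zeroed(self):
        g = BipartiteGraph(["d1", "d2"], ["m1", "m2"], {(0, 0): 1.0})
        emb = train_bine(g, BineConfig(dim=8, epochs=3, seed=0, min_walks_per_node=1))
        assert not emb.drug_vecs[1].any()
        assert not emb.mirna_vecs[1].any()
        assert emb.drug_vecs[0].any()

    def test_empty_graph_errors(self):
        g = BipartiteGraph(["d"], ["m"], {})
        with pytest.raises(ValueError):
            train_bine(g, BineConfig())

    def test_lsh_strategy_trains(self):
        g = self.two_block_graph()
        cfg = BineConfig(dim=8, epochs=2, seed=1, min_walks_per_node=1,
                         negative_strategy="lsh")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = train_bine(g, cfg)
        assert np.all(np.isfinite(emb.drug_vecs))


class TestLinkPredictionRecovery:
    def test_holdout_auc_on_planted_blocks(self):
        """Ranking 10% held-out edges by sigma(d.m) on a separable 2-block
        fixture recovers them with AUC >= 0.90 (mean over 5 seeds)."""
        from sklearn.metrics import roc_auc_score

        from mirdrug.fixtures import FixtureSpec, gen_bipartite
        from mirdrug.graph import restrict_to_training

        aucs = []
        for seed in range(5):
            spec = FixtureSpec(n_drugs=30, n_mirnas=60, p_within=0.9, p_between=0.01, seed=seed)
            g, _, _ = gen_bipartite(spec)
            rng = np.random.default_rng(1000 + seed)
            edges = sorted(g.edges)
            held_idx = rng.choice(len(edges), size=len(edges) // 10, replace=False)
            held = [edges[k] for k in held_idx]
            g_train = restrict_to_training(g, set(edges) - set(held))
            emb = train_bine(g_train, BineConfig(seed=seed))
            non = []
            while len(non) < len(held):
                i, j = int(rng.integers(g.n_drugs)), int(rng.integers(g.n_mirnas))
                if (i, j) not in g.edges:
                    non.append((i, j))
            pairs = held + non
            y = [1] * len(held) + [0] * len(non)
            s = [float(emb.drug_vecs[i] @ emb.mirna_vecs[j]) for i, j in pairs]
            aucs.append(roc_auc_score(y, s))
        assert np.mean(aucs) >= 0.90


class TestWord2VecIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        ids = ["a", "b", "c"]
        mat = rng.normal(size=(3, 5))
        path = tmp_path / "emb.w2v"
        save_word2vec(path, ids, mat)
        ids2, mat2 = load_word2vec(path)
        assert ids2 == ids
        assert np.array_equal(mat, mat2)  # repr() round-trips floats exactly

    def test_header_format(self, tmp_path):
        path = tmp_path / "emb.w2v"
        save_word2vec(path, ["x"], np.zeros((1, 4)))
        assert path.read_text().splitlines()[0] == "1 4"

    def test_from_word2vec_pluggable(self, tmp_path):
        rng = np.random.default_rng(1)
        dv, mv = rng.normal(size=(2, 3)), rng.normal(size=(4, 3))
        save_word2vec(tmp_path / "d.w2v", ["d1", "d2"], dv)
        save_word2vec(tmp_path / "m.w2v", ["m1", "m2", "m3", "m4"], mv)
        emb = NodeEmbeddingTable.from_word2vec(
            tmp_path / "d.w2v", tmp_path / "m.w2v", ["d2", "d1"], ["m4", "m1", "m2", "m3"]
        )
        assert np.array_equal(emb.drug_vecs[0], dv[1])
        assert np.array_equal(emb.mirna_vecs[0], mv[3])


def test_config_validation():
    with pytest.raises(ValueError):
        BineConfig(dim=0)
    with pytest.raises(ValueError):
        BineConfig(stop_prob=0.0)
    with pytest.raises(ValueError):
        BineConfig(min_walks_per_node=5, max_walks_per_node=2)
    with pytest.raises(ValueError):
        BineConfig(alpha=-1.0)
    with pytest.raises(ValueError):
        BineConfig(negative_strategy="bogus")
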