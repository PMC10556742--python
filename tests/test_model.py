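"""Embedding model: closed forms, attention normalization, and a full
forward-pass check against a non-vectorized scalar reimplementation."""

import cmath
import math

import numpy as np
import pytest

from comorbnet._autodiff import Tensor
from comorbnet.graph import NodeType, build_graph
from comorbnet.metapaths import SCHEMAS, enumerate_metapath_instances
from comorbnet.model import EmbeddingConfig, GraphIndex, encode_instance, \
    forward_embed, init_params, inter_metapath_aggregate, \
    intra_metapath_aggregate, project_node_features, project_output, \
    summarize_metapath


def zero_phase_params(params):
    for k in params:
        if k.startswith("theta_"):
            params[k].data[:] = 0.0
    return params


class TestProjection:
    def test_identity_projection(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        out = project_node_features(x, np.eye(3))
        np.testing.assert_allclose(out.data, x)

    def test_hand_matrix_product(self):
        w = np.array([[1.0, 2.0], [0.0, -1.0], [3.0, 0.5]])  # 3 -> 2
        x = np.array([[2.0, 1.0, -1.0]])
        out = project_node_features(x, w)
        np.testing.assert_allclose(out.data, [[2 * 1 + 0 - 3,
                                               4 - 1 - 0.5]])

    def test_shape_mismatch_fatal(self):
        with pytest.raises(ValueError, match="does not match"):
            project_node_features(np.zeros((2, 3)), np.zeros((4, 5)))


class TestRotationEncoder:
    def test_zero_phase_reduces_to_mean(self):
        """With all relation phases 0 the encoder is the arithmetic mean of
        the instance's node vectors, for instance lengths 2-7."""
        rng = np.random.default_rng(5)
        cfg = EmbeddingConfig(hidden_dim=6, heads=2, seed=0)
        for sid, schema in SCHEMAS.items():
            for _ in range(5):
                vecs = rng.normal(size=(schema.length, 6))
                params = {f"theta_{et.value}": Tensor(np.zeros(3))
                          for et in set(schema.edge_types)}
                out = encode_instance(vecs, schema, params)
                np.testing.assert_allclose(out, vecs.mean(axis=0),
                                           atol=1e-12)

    def test_identical_vectors_zero_phase_fixed_point(self):
        v = np.arange(4.0)
        params = {"theta_DG": Tensor(np.zeros(2))}
        out = encode_instance(np.stack([v, v, v]), SCHEMAS["M1"], params)
        np.testing.assert_allclose(out, v)

    def test_pi_phase_hand_computation(self):
        """3-node instance with phase pi on both hops, verified component by
        component with scalar complex arithmetic."""
        schema = SCHEMAS["M1"]  # D-G-D: DG forward then DG reverse
        theta = np.full(2, np.pi)
        params = {"theta_DG": Tensor(theta)}
        rng = np.random.default_rng(1)
        vecs = rng.normal(size=(3, 4))

        out = encode_instance(vecs, schema, params)
        for k in range(2):
            h = [complex(v[2 * k], v[2 * k + 1]) for v in vecs]
            o = h[0]
            o = h[1] + o * cmath.exp(1j * np.pi)       # forward hop
            o = h[2] + o * cmath.exp(-1j * np.pi)      # reverse hop conjugates
            o /= 3
            assert out[2 * k] == pytest.approx(o.real, abs=1e-12)
            assert out[2 * k + 1] == pytest.approx(o.imag, abs=1e-12)

    def test_missing_relation_vector_fatal(self):
        with pytest.raises(ValueError, match="no relation vector"):
            encode_instance(np.zeros((3, 4)), SCHEMAS["M1"], {})


class TestIntraAggregation:
    cfg = EmbeddingConfig(hidden_dim=4, heads=2, dropout=0.0, seed=0)

    def test_softmax_of_singleton_is_identity(self):
        rng = np.random.default_rng(2)
        h_inst = Tensor(rng.normal(size=(1, 4)))
        h_tgt = Tensor(rng.normal(size=(1, 4)))
        a = Tensor(rng.normal(size=(2, 4)))
        out, alpha = intra_metapath_aggregate(
            h_inst, h_tgt, np.array([0]), 1, a, self.cfg, return_alpha=True)
        np.testing.assert_allclose(alpha.data, 1.0)
        # ELU(h) of the single instance vector
        expected = np.where(h_inst.data > 0, h_inst.data,
                            np.expm1(h_inst.data))
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_identical_instances_split_weight_evenly(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=4)
        h_inst = Tensor(np.stack([v, v]))
        h_tgt = Tensor(np.stack([rng.normal(size=4)] * 2))
        a = Tensor(rng.normal(size=(2, 4)))
        _, alpha = intra_metapath_aggregate(
            h_inst, h_tgt, np.array([0, 0]), 1, a, self.cfg,
            return_alpha=True)
        np.testing.assert_allclose(alpha.data, 0.5, atol=1e-12)

    def test_three_instance_softmax_matches_hand_exp_normalize(self):
        """Scalar exp-normalize oracle on fixed toy logits (1 head)."""
        cfg = EmbeddingConfig(hidden_dim=2, heads=1, dropout=0.0)
        h_inst = Tensor(np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        h_tgt = Tensor(np.tile([0.5, -0.5], (3, 1)))
        a = Tensor(np.array([[0.1, 0.2, 0.3, 0.4]]))
        _, alpha = intra_metapath_aggregate(
            h_inst, h_tgt, np.zeros(3, dtype=int), 1, a, cfg,
            return_alpha=True)
        logits = []
        for h in ([1, 0], [0, 1], [1, 1]):
            z = 0.1 * 0.5 + 0.2 * -0.5 + 0.3 * h[0] + 0.4 * h[1]
            logits.append(z if z > 0 else 0.2 * z)
        e = [math.exp(z) for z in logits]
        expected = [x / sum(e) for x in e]
        np.testing.assert_allclose(alpha.data.ravel(), expected, atol=1e-12)

    def test_starved_target_gets_activation_of_zero(self):
        out = intra_metapath_aggregate(
            Tensor(np.zeros((0, 4))), Tensor(np.zeros((0, 4))),
            np.zeros(0, dtype=int), 3, Tensor(np.zeros((2, 4))), self.cfg)
        np.testing.assert_allclose(out.data, 0.0)

    def test_attention_sums_to_one_per_target_and_head(self):
        rng = np.random.default_rng(8)
        n, n_tgt = 40, 6
        seg = np.sort(rng.integers(0, n_tgt, n))
        cfg = EmbeddingConfig(hidden_dim=8, heads=4, dropout=0.0)
        _, alpha = intra_metapath_aggregate(
            Tensor(rng.normal(size=(n, 8))), Tensor(rng.normal(size=(n, 8))),
            seg, n_tgt, Tensor(rng.normal(size=(4, 4))), cfg,
            return_alpha=True)
        for t in np.unique(seg):
            np.testing.assert_allclose(alpha.data[seg == t].sum(axis=0),
                                       1.0, atol=1e-6)

    def test_instance_order_permutation_invariance(self):
        rng = np.random.default_rng(9)
        n = 12
        h = rng.normal(size=(n, 4))
        ht = rng.normal(size=(n, 4))
        seg = np.zeros(n, dtype=int)
        a = Tensor(rng.normal(size=(2, 4)))
        out1 = intra_metapath_aggregate(Tensor(h), Tensor(ht), seg, 1, a,
                                        self.cfg)
        perm = rng.permutation(n)
        out2 = intra_metapath_aggregate(Tensor(h[perm]), Tensor(ht[perm]),
                                        seg, 1, a, self.cfg)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-6)


class TestInterAggregation:
    def test_summary_closed_forms(self):
        m = Tensor(np.eye(3))
        b = Tensor(np.zeros(3))
        assert np.allclose(
            summarize_metapath(Tensor(np.zeros((1, 3))), m, b).data, 0.0)
        h = np.array([0.3, -1.0, 2.0])
        out = summarize_metapath(Tensor(np.tile(h, (5, 1))), m, b)
        np.testing.assert_allclose(out.data, np.tanh(h), atol=1e-12)

    def test_two_node_hand_mean_of_tanh(self):
        rng = np.random.default_rng(4)
        m = Tensor(rng.normal(size=(3, 2)))
        b = Tensor(rng.normal(size=2))
        h = rng.normal(size=(2, 3))
        out = summarize_metapath(Tensor(h), m, b)
        expected = (np.tanh(h[0] @ m.data + b.data)
                    + np.tanh(h[1] @ m.data + b.data)) / 2
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_single_schema_degenerates_to_identity(self):
        rng = np.random.default_rng(5)
        h = Tensor(rng.normal(size=(4, 3)))
        s = Tensor(rng.normal(size=2))
        q = Tensor(rng.normal(size=2))
        fused, beta = inter_metapath_aggregate([h], [s], q, return_beta=True)
        np.testing.assert_allclose(beta.data, [1.0])
        np.testing.assert_allclose(fused.data, h.data)

    def test_zero_query_gives_uniform_weights(self):
        rng = np.random.default_rng(6)
        hs = [Tensor(rng.normal(size=(4, 3))) for _ in range(4)]
        ss = [Tensor(rng.normal(size=2)) for _ in range(4)]
        fused, beta = inter_metapath_aggregate(hs, ss, Tensor(np.zeros(2)),
                                               return_beta=True)
        np.testing.assert_allclose(beta.data, 0.25, atol=1e-12)
        np.testing.assert_allclose(
            fused.data, sum(h.data for h in hs) / 4, atol=1e-12)

    def test_four_schema_weights_match_hand_exp_normalize(self):
        q = Tensor(np.array([1.0, -1.0]))
        ss = [Tensor(np.array([s1, s2]))
              for s1, s2 in [(0.2, 0.1), (-0.3, 0.4), (0.0, 0.0), (1.0, 0.5)]]
        hs = [Tensor(np.zeros((1, 2))) for _ in ss]
        _, beta = inter_metapath_aggregate(hs, ss, q, return_beta=True)
        logits = [0.2 - 0.1, -0.3 - 0.4, 0.0, 1.0 - 0.5]
        e = [math.exp(z) for z in logits]
        np.testing.assert_allclose(beta.data, [x / sum(e) for x in e],
                                   atol=1e-12)
        assert beta.data.sum() == pytest.approx(1.0, abs=1e-6)


class TestOutputProjection:
    def test_hand_two_by_two(self):
        w = np.array([[1.0, -2.0], [0.5, 0.0]])
        x = Tensor(np.array([[2.0, -1.0]]))
        out = project_output(x, Tensor(w), activation="identity")
        np.testing.assert_allclose(out.data, [[2 - 0.5, -4 + 0]])

    def test_default_output_dimension(self, default_graph):
        cfg = EmbeddingConfig(seed=0)
        index = GraphIndex(default_graph, cfg)
        params = init_params(index, cfg)
        emb = forward_embed(index, params, cfg)
        assert emb.shape == (index.n_diseases, 64)


class TestForwardPass:
    def test_eval_mode_is_deterministic(self, toy_graph):
        cfg = EmbeddingConfig(hidden_dim=8, heads=2, summary_dim=4,
                              out_dim=4, seed=1)
        index = GraphIndex(toy_graph, cfg)
        params = init_params(index, cfg)
        e1 = forward_embed(index, params, cfg).data
        e2 = forward_embed(index, params, cfg).data
        assert np.array_equal(e1, e2)

    def test_isomorphic_components_get_identical_embeddings(self):
        """Two disjoint copies of the same motif with tied node features
        embed identically."""
        g = build_graph(
            dg=[("a_d1", "a_g1"), ("a_d2", "a_g1"),
                ("b_d1", "b_g1"), ("b_d2", "b_g1")],
            gg=[], gm=[("a_g1", "a_m1"), ("b_g1", "b_m1")],
            mp=[("a_m1", "a_p1"), ("b_m1", "b_p1")])
        cfg = EmbeddingConfig(hidden_dim=4, heads=2, summary_dim=3,
                              out_dim=3, seed=0)
        index = GraphIndex(g, cfg)
        params = init_params(index, cfg)
        # tie features across the two copies (a_* nodes come first per type)
        for t in NodeType:
            x = params.get(f"X_{t.value}")
            if x is not None and x.shape[0] == 2:
                x.data[1] = x.data[0]
        for pos in range(2):
            params["X_DISEASE"].data[pos + 2] = params["X_DISEASE"].data[pos]
        emb = forward_embed(index, params, cfg).data
        ids = index.disease_ids
        np.testing.assert_allclose(emb[ids.index("a_d1")],
                                   emb[ids.index("b_d1")], atol=1e-10)
        np.testing.assert_allclose(emb[ids.index("a_d2")],
                                   emb[ids.index("b_d2")], atol=1e-10)

    def test_forward_matches_scalar_reimplementation(self, toy_graph):
        """Vectorized forward equals a straight-line per-scalar evaluation
        of projection, rotation encoding, both attention stages and the
        output map on a small graph."""
        cfg = EmbeddingConfig(hidden_dim=4, heads=2, summary_dim=3,
                              out_dim=3, dropout=0.0, seed=3,
                              instance_cap=None)
        index = GraphIndex(toy_graph, cfg)
        params = init_params(index, cfg)
        emb = forward_embed(index, params, cfg).data
        oracle = scalar_forward(toy_graph, params, cfg)
        for i, d in enumerate(index.disease_ids):
            np.testing.assert_allclose(emb[i], oracle[d], atol=1e-5)


def scalar_forward(graph, params, cfg):
    """Non-vectorized oracle: dict-of-floats evaluation of the whole model."""
    def elu(x):
        return x if x > 0 else math.expm1(x)

    def leaky(x):
        return x if x > 0 else 0.2 * x

    d = cfg.hidden_dim
    heads, hd = cfg.heads, cfg.hidden_dim // cfg.heads
    # projection h' = x W, one scalar at a time
    h = {}
    for t in NodeType:
        nodes = graph.nodes_of_type(t)
        if not nodes:
            continue
        x = params[f"X_{t.value}"].data
        w = params[f"W_{t.value}"].data
        for i, node in enumerate(nodes):
            h[node] = [sum(x[i][k] * w[k][j] for k in range(x.shape[1]))
                       for j in range(d)]
    h_p_all = {}
    summaries = {}
    diseases = graph.nodes_of_type(NodeType.DISEASE)
    for sid in cfg.metapaths:
        schema = SCHEMAS[sid]
        h_p = {}
        for target in diseases:
            insts = enumerate_metapath_instances(graph, schema, target,
                                                 cap=None)
            if not insts:
                h_p[target] = [elu(0.0)] * d
                continue
            encoded = []
            for inst in insts:
                o = [complex(h[inst[0]][2 * k], h[inst[0]][2 * k + 1])
                     for k in range(d // 2)]
                for pos, (et, sign) in enumerate(
                        zip(schema.edge_types, schema.edge_signs), start=1):
                    theta = params[f"theta_{et.value}"].data
                    node = inst[pos]
                    o = [complex(h[node][2 * k], h[node][2 * k + 1])
                         + o[k] * cmath.exp(1j * sign * theta[k])
                         for k in range(d // 2)]
                vec = []
                for z in o:
                    vec.extend([z.real / schema.length,
                                z.imag / schema.length])
                encoded.append(vec)
            out_vec = []
            a = params[f"a_{sid}"].data
            for head in range(heads):
                sl = slice(head * hd, (head + 1) * hd)
                logits = []
                for vec in encoded:
                    catted = list(h[target][sl]) + list(vec[sl])
                    logits.append(leaky(sum(a[head][j] * catted[j]
                                            for j in range(2 * hd))))
                mx = max(logits)
                exps = [math.exp(z - mx) for z in logits]
                alphas = [e / sum(exps) for e in exps]
                agg = [sum(alphas[n] * encoded[n][sl][j]
                           for n in range(len(encoded))) for j in range(hd)]
                out_vec.extend(agg)
            h_p[target] = [elu(v) for v in out_vec]
        h_p_all[sid] = h_p
        m_a, b_a = params["M_A"].data, params["b_A"].data
        s = [0.0] * cfg.summary_dim
        for target in diseases:
            for j in range(cfg.summary_dim):
                s[j] += math.tanh(sum(h_p[target][k] * m_a[k][j]
                                      for k in range(d)) + b_a[j])
        summaries[sid] = [v / len(diseases) for v in s]
    q = params["q_A"].data
    logits = [sum(q[j] * summaries[sid][j] for j in range(cfg.summary_dim))
              for sid in cfg.metapaths]
    mx = max(logits)
    exps = [math.exp(z - mx) for z in logits]
    betas = [e / sum(exps) for e in exps]
    w_o = params["W_o"].data
    out = {}
    for target in diseases:
        fused = [sum(betas[i] * h_p_all[sid][target][k]
                     for i, sid in enumerate(cfg.metapaths))
                 for k in range(d)]
        out[target] = [elu(sum(fused[k] * w_o[k][j] for k in range(d)))
                       for j in range(cfg.out_dim)]
    return out


def test_one_hot_feature_mode_forward(toy_graph):
    """One-hot node features: identity content, projection learns the rest."""
    cfg = EmbeddingConfig(hidden_dim=4, heads=2, summary_dim=3, out_dim=3,
                          feature_mode="onehot", seed=0)
    index = GraphIndex(toy_graph, cfg)
    params = init_params(index, cfg)
    n_dis = len(index.disease_ids)
    assert params["X_DISEASE"].data.shape == (n_dis, n_dis)
    assert not params["X_DISEASE"].requires_grad
    assert params["W_DISEASE"].data.shape == (n_dis, 4)
    emb = forward_embed(index, params, cfg)
    assert emb.shape == (n_dis, 3)
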