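"""Structural correctness of the TriHAT denoiser.

The load-bearing checks are permutation equivariance of the full
forward pass (gene order is arbitrary, so predictions must follow any
relabeling), softmax normalization of every attention, and loop oracles
for the FiLM / GATv2 / GPoX blocks.
"""

import numpy as np
import pytest

import planet
from planet._autodiff import Linear, Tensor
from planet.denoiser import (GATv2Layer, TriHAT, film, node_features,
                             sinusoidal_embedding)


@pytest.fixture(scope="module")
def small_net(tiny_model_config):
    return TriHAT(tiny_model_config, seed=3)


def random_inputs(n=6, n_cells=30, seed=0, n_tf=3):
    rng = np.random.default_rng(seed)
    tf_mask = np.zeros(n, dtype=bool)
    tf_mask[:n_tf] = True
    e_t = (rng.random((n, n)) < 0.3).astype(np.int8)
    np.fill_diagonal(e_t, 0)
    e_t[~tf_mask] = 0
    expr = planet.ExpressionMatrix(rng.gamma(2.0, 1.0, size=(n_cells, n)),
                                   [f"g{i}" for i in range(n)])
    return e_t, expr, tf_mask


class TestFilm:
    def test_identity_at_zero_params(self):
        rng = np.random.default_rng(0)
        lin1 = Linear(4, 3, rng)
        lin2 = Linear(4, 3, rng)
        lin1.weight.data[:] = 0
        lin2.weight.data[:] = 0
        b = Tensor(rng.normal(size=(5, 3)))
        out = film(Tensor(rng.normal(size=4)), b, lin1, lin2)
        assert np.allclose(out.data, b.data)

    def test_pure_scaling(self):
        rng = np.random.default_rng(1)
        lin1 = Linear(2, 3, rng)
        lin2 = Linear(2, 3, rng)
        lin1.weight.data[:] = 0
        lin1.bias.data[:] = 0
        lin2.weight.data[:] = 0
        lin2.bias.data[:] = 0.5
        b = Tensor(rng.normal(size=(4, 3)))
        out = film(Tensor(np.zeros(2)), b, lin1, lin2)
        assert np.allclose(out.data, 1.5 * b.data)

    def test_scalar_recomputation(self):
        rng = np.random.default_rng(2)
        lin1, lin2 = Linear(3, 3, rng), Linear(3, 3, rng)
        a, b = rng.normal(size=3), rng.normal(size=3)
        out = film(Tensor(a), Tensor(b), lin1, lin2)
        expect = np.array([
            (a @ lin1.weight.data[:, j] + lin1.bias.data[j]) +
            (a @ lin2.weight.data[:, j] + lin2.bias.data[j]) * b[j] + b[j]
            for j in range(3)])
        assert np.allclose(out.data, expect, atol=1e-7)


class TestGATv2:
    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        layer = GATv2Layer(5, 4, 2, 0.2, rng, concat_heads=True)
        adj = (rng.random((7, 7)) < 0.3).astype(int)
        alpha, _ = layer.attention(Tensor(rng.normal(size=(7, 5))), adj)
        assert np.allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)

    def test_isolated_node_attends_to_self_only(self):
        rng = np.random.default_rng(1)
        layer = GATv2Layer(3, 4, 1, 0.2, rng, concat_heads=True)
        X = Tensor(rng.normal(size=(1, 3)))
        out = layer(X, np.zeros((1, 1), dtype=int))
        expect = X.data @ layer.lin_r.weight.data + layer.lin_r.bias.data
        assert np.allclose(out.data, expect, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        layer = GATv2Layer(5, 4, 2, 0.2, rng, concat_heads=True)
        n = 7
        X = rng.normal(size=(n, 5))
        adj = (rng.random((n, n)) < 0.4).astype(int)
        perm = rng.permutation(n)
        base = layer(Tensor(X), adj).data
        permuted = layer(Tensor(X[perm]), adj[np.ix_(perm, perm)]).data
        assert np.allclose(permuted, base[perm], atol=1e-5)


class TestTimeGate:
    def test_endpoints_and_arithmetic(self, small_net):
        rng = np.random.default_rng(3)
        d = small_net.config.d_x
        gate = small_net.gate1
        h = Tensor(rng.normal(size=(5, d)))
        x = Tensor(rng.normal(size=(5, d)))
        t_vec = Tensor(rng.normal(size=small_net.config.d_t))
        # force the gate by saturating the linear layer's bias
        gate.lin_gate.weight.data[:] = 0
        gate.lin_gate.bias.data[:] = 40.0   # sigmoid -> 1: pure skip
        assert np.allclose(gate.blend(h, x, t_vec).data, x.data, atol=1e-9)
        gate.lin_gate.bias.data[:] = -40.0  # sigmoid -> 0: pure aggregation
        assert np.allclose(gate.blend(h, x, t_vec).data, h.data, atol=1e-9)
        gate.lin_gate.bias.data[:] = 0.3
        g = 1 / (1 + np.exp(-0.3))
        assert np.allclose(gate.blend(h, x, t_vec).data,
                           (1 - g) * h.data + g * x.data, atol=1e-10)


class TestTransformerLayer:
    def test_node_attention_single_gene_is_value_projection(self, small_net):
        layer = small_net.layers[0]
        x = np.random.default_rng(4).normal(size=(1, small_net.config.d_x))
        out = layer.node_attention(Tensor(x))
        v = x @ layer.lin_v.weight.data + layer.lin_v.bias.data
        expect = v @ layer.lin_o.weight.data + layer.lin_o.bias.data
        assert np.allclose(out.data, expect, atol=1e-10)

    def test_cross_attention_rows_normalized(self, small_net):
        rng = np.random.default_rng(5)
        layer = small_net.layers[0]
        d_e = small_net.config.d_e
        e_self = Tensor(rng.normal(size=(4, 4, d_e)))
        e_feed = Tensor(rng.normal(size=(4, 4, d_e)))
        _, att = layer.cross_attention(e_self, e_feed)
        assert np.allclose(att.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_feedback_edge_state_shifts_edge_features(self, small_net):
        """Pairs fed back as edges get different features than non-edges."""
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(6)
        n = 23  # ~500 candidate pairs
        e_t, expr, tf_mask = random_inputs(n=n, n_cells=40, seed=6, n_tf=n)
        np.fill_diagonal(e_t, 0)
        layer = small_net.layers[0]
        cand = np.ones((n, n), dtype=bool)
        np.fill_diagonal(cand, False)
        E0 = small_net._edge_init(e_t, cand)
        X = Tensor(rng.normal(size=(n, small_net.config.d_x)))
        t_vec = Tensor(rng.normal(size=small_net.config.d_t))
        e_hat = layer.update_edges(X, E0, t_vec)
        norms = np.linalg.norm(e_hat.data, axis=-1)
        a = norms[cand & (e_t == 1)]
        b = norms[cand & (e_t == 0)]
        assert ttest_ind(a, b).pvalue < 0.01

    def test_gpox_matches_explicit_loop(self, small_net):
        rng = np.random.default_rng(7)
        layer = small_net.layers[0]
        d = small_net.config.d_x
        X = rng.normal(size=(6, d))
        out = layer.gpox(Tensor(X)).data
        pooled = np.zeros(d)
        for i in range(6):
            g = 1 / (1 + np.exp(-(X[i] @ layer.gpox_gate.weight.data
                                  + layer.gpox_gate.bias.data)))
            pooled += g * X[i]
        expect = pooled @ layer.gpox_out.weight.data + layer.gpox_out.bias.data
        assert np.allclose(out, expect, atol=1e-6)

    def test_gpox_single_node_saturated_gate(self, small_net):
        layer = small_net.layers[0]
        d = small_net.config.d_x
        x = np.random.default_rng(8).normal(size=(1, d))
        old_bias = layer.gpox_gate.bias.data.copy()
        old_w = layer.gpox_gate.weight.data.copy()
        layer.gpox_gate.weight.data[:] = 0
        layer.gpox_gate.bias.data[:] = 50.0  # gate -> 1
        out = layer.gpox(Tensor(x)).data
        layer.gpox_gate.bias.data = old_bias
        layer.gpox_gate.weight.data = old_w
        expect = x[0] @ layer.gpox_out.weight.data + layer.gpox_out.bias.data
        assert np.allclose(out, expect, atol=1e-8)

    def test_time_update_additive_decomposition(self, small_net):
        """Zero features and biases leave only the linear time term."""
        layer = small_net.layers[0]
        cfg = small_net.config
        rng = np.random.default_rng(9)
        t_vec = Tensor(rng.normal(size=cfg.d_t))
        X = Tensor(np.zeros((4, cfg.d_x)))
        E = Tensor(np.zeros((4, 4, cfg.d_e)))
        cand = np.ones((4, 4), dtype=bool)
        np.fill_diagonal(cand, False)
        saved = [layer.gpox_out.bias.data.copy(), layer.atte_val.bias.data.copy()]
        layer.gpox_out.bias.data[:] = 0
        layer.atte_val.bias.data[:] = 0
        out = layer.update_time(X, E, t_vec, cand).data
        expect = t_vec.data @ layer.lin_t.weight.data + layer.lin_t.bias.data
        layer.gpox_out.bias.data, layer.atte_val.bias.data = saved
        assert np.allclose(out, expect, atol=1e-10)


class TestFullForward:
    def test_output_shape_and_mask_sentinel(self, small_net):
        e_t, expr, tf_mask = random_inputs()
        logits = small_net.forward(e_t, expr, 10, tf_mask, T=100)
        n = len(tf_mask)
        assert logits.shape == (n, n, 2)
        probs = logits.softmax(axis=-1).data[..., 1]
        cand = np.repeat(tf_mask[:, None], n, axis=1)
        np.fill_diagonal(cand, False)
        assert np.all(probs[~cand] == 0)

    def test_bit_stable_repeat(self, small_net):
        e_t, expr, tf_mask = random_inputs(seed=1)
        a = small_net.forward(e_t, expr, 7, tf_mask, T=100).data
        b = small_net.forward(e_t, expr, 7, tf_mask, T=100).data
        assert np.array_equal(a, b)

    def test_joint_permutation_equivariance(self, tiny_model_config):
        """Relabeling genes everywhere permutes the logits identically."""
        net = TriHAT(tiny_model_config, seed=11)
        n = 6
        e_t, expr, tf_mask = random_inputs(n=n, seed=12, n_tf=6)
        rng = np.random.default_rng(13)
        perm = rng.permutation(n)
        base = net.forward(e_t, expr, 30, tf_mask, T=100).data
        expr_p = planet.ExpressionMatrix(expr.values[:, perm],
                                         [expr.genes[i] for i in perm])
        out_p = net.forward(e_t[np.ix_(perm, perm)], expr_p, 30,
                            tf_mask[perm], T=100).data
        assert np.allclose(out_p, base[np.ix_(perm, perm)], atol=1e-4)

    def test_gene_count_mismatch_raises(self, small_net):
        e_t, expr, tf_mask = random_inputs(n=6)
        bad = planet.ExpressionMatrix(expr.values[:, :5], expr.genes[:5])
        with pytest.raises(planet.AlignmentError):
            small_net.forward(e_t, bad, 5, tf_mask, T=100)

    def test_all_parameters_receive_gradient(self, tiny_model_config):
        net = TriHAT(tiny_model_config, seed=21)
        e_t, expr, tf_mask = random_inputs(seed=22)
        logits = net.forward(e_t, expr, 40, tf_mask, T=100)
        cand = np.repeat(tf_mask[:, None], len(tf_mask), axis=1)
        np.fill_diagonal(cand, False)
        loss = planet.training_loss(logits, e_t, cand)
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None and np.abs(p.grad).sum() > 0, name


class TestCheckpoint:
    def test_save_load_bit_exact(self, tiny_model_config, tmp_path):
        net = TriHAT(tiny_model_config, seed=31)
        e_t, expr, tf_mask = random_inputs(seed=32)
        before = net.forward(e_t, expr, 9, tf_mask, T=100).data
        path = tmp_path / "model.ckpt"
        planet.save_checkpoint(net, path, meta={"fingerprint": "x"})
        loaded, meta = planet.load_checkpoint(path)
        assert meta == {"fingerprint": "x"}
        after = loaded.forward(e_t, expr, 9, tf_mask, T=100).data
        assert np.array_equal(before, after)

    def test_reject_foreign_file(self, tmp_path):
        p = tmp_path / "bogus.ckpt"
        p.write_bytes((8).to_bytes(8, "little") + b'{"a": 1}')
        with pytest.raises(ValueError):
            planet.load_checkpoint(p)


class TestFeaturizer:
    def test_time_embedding_deterministic_and_distinct(self):
        a = sinusoidal_embedding(5, 32, 100)
        b = sinusoidal_embedding(5, 32, 100)
        c = sinusoidal_embedding(50, 32, 100)
        assert np.array_equal(a, b)
        assert not np.allclose(a, c)

    def test_node_features_shape_and_tf_flag(self):
        _, expr, tf_mask = random_inputs(n=8, n_cells=50, n_tf=4)
        feats = node_features(expr, tf_mask, p_profile=16)
        assert feats.shape == (8, 16 + 7)
        flags = feats[:, 6]  # standardized TF indicator column
        assert len(np.unique(np.round(flags, 6))) == 2

    def test_profile_projection_preserves_correlation_order(self):
        """Inner products of projected profiles track gene-gene correlation."""
        rng = np.random.default_rng(40)
        base = rng.normal(size=(200, 1))
        v = np.abs(np.concatenate([base + 0.1 * rng.normal(size=(200, 1)),
                                   base + 0.1 * rng.normal(size=(200, 1)),
                                   rng.normal(size=(200, 1))], axis=1)) + 0.1
        expr = planet.ExpressionMatrix(v, ["a", "b", "c"])
        z = node_features(expr, np.array([True, True, True]), 64)[:, 7:]
        corr_ab = z[0] @ z[1]
        corr_ac = z[0] @ z[2]
        assert corr_ab > corr_ac
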