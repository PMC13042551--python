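import numpy as np
import pytest

from s3rl.gtn import (GTNAutoencoder, GTNConfig, GTNLayer, mask_spots,
                      reconstruction_loss, reconstruction_loss_t,
                      topological_loss, topological_loss_t)
from s3rl.nn import Tensor


def dense_gtn_oracle(Z, adj, layer):
    """Dense reimplementation of the gated attention layer for small graphs."""
    n, _ = Z.shape
    W1, W2 = layer.W1.data, layer.W2.data
    q, k = Z @ layer.Wq.data, Z @ layer.Wk.data
    self_t = Z @ W1
    out = np.zeros((n, layer.d_out))
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size:
            logits = np.array([q[i] @ k[j] for j in nbrs]) / np.sqrt(layer.d_attn)
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            agg = sum(a * (Z[j] @ W2) for a, j in zip(alpha, nbrs))
        else:
            agg = np.zeros(layer.d_out)
        gate_in = (self_t[i] @ layer.g_self.data + agg @ layer.g_agg.data
                   + (self_t[i] - agg) @ layer.g_diff.data + layer.g_bias.data)
        beta = 1.0 / (1.0 + np.exp(-gate_in))
        pre = beta * self_t[i] + (1 - beta) * agg
        out[i] = np.where(pre > 0, pre, np.exp(np.minimum(pre, 0)) - 1.0)
    return out


def pairs_from_adj(adj):
    src, dst = np.nonzero(adj)
    return np.column_stack([src, dst])


class TestGTNLayer:
    def test_isolated_node_with_identity_selfpath_passes_through(self, rng):
        layer = GTNLayer(4, 4, rng)
        layer.W1.data = np.eye(4)
        layer.g_bias.data = np.array([1e3])  # force beta ≈ 1
        x = np.abs(rng.normal(size=(1, 4)))  # ELU is identity on ≥ 0
        out = layer(Tensor(x), np.empty((0, 2), dtype=np.intp))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_single_neighbor_attention_weight_is_one(self, rng):
        """With one neighbor, softmax gives α=1 whatever the logits, so the
        aggregate equals W2 z_j exactly."""
        layer = GTNLayer(3, 3, rng)
        layer.g_bias.data = np.array([-1e3])  # beta ≈ 0: output = ELU(agg)
        Z = rng.normal(size=(2, 3))
        pairs = np.array([[1, 0]])  # node 0 receives only from node 1
        out = layer(Tensor(Z), pairs)
        agg = Z[1] @ layer.W2.data
        expected = np.where(agg > 0, agg, np.exp(np.minimum(agg, 0)) - 1)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-9)

    def test_matches_dense_oracle_on_path_graph(self, rng):
        layer = GTNLayer(5, 4, rng)
        for p in layer.params:
            p.data = rng.normal(scale=0.3, size=p.data.shape)
        Z = rng.normal(size=(3, 5))
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        out = layer(Tensor(Z), pairs_from_adj(adj))
        np.testing.assert_allclose(out.data, dense_gtn_oracle(Z, adj, layer),
                                   atol=1e-6)

    def test_matches_dense_oracle_on_random_graph(self, rng):
        layer = GTNLayer(6, 5, rng)
        Z = rng.normal(size=(8, 6))
        adj = (rng.random((8, 8)) < 0.3)
        adj = (adj | adj.T) & ~np.eye(8, dtype=bool)
        out = layer(Tensor(Z), pairs_from_adj(adj))
        np.testing.assert_allclose(out.data, dense_gtn_oracle(Z, adj, layer),
                                   atol=1e-6)

    def test_permutation_equivariance(self, rng):
        layer = GTNLayer(6, 5, rng)
        Z = rng.normal(size=(10, 6))
        adj = (rng.random((10, 10)) < 0.25)
        adj = (adj | adj.T) & ~np.eye(10, dtype=bool)
        out = layer(Tensor(Z), pairs_from_adj(adj)).data
        perm = rng.permutation(10)
        out_p = layer(Tensor(Z[perm]), pairs_from_adj(adj[np.ix_(perm, perm)])).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-9)


class TestMasking:
    def test_zero_ratio_is_identity(self, rng):
        X = rng.normal(size=(6, 3))
        out, idx = mask_spots(X, 0.0, np.zeros(3), rng)
        np.testing.assert_array_equal(out, X)
        assert idx.size == 0

    def test_floor_count_and_token_rows(self, rng):
        X = np.ones((4, 3))
        token = np.full(3, -7.0)
        out, idx = mask_spots(X, 0.5, token, rng)
        assert idx.size == 2
        np.testing.assert_array_equal(out[idx], np.tile(token, (2, 1)))
        untouched = np.setdiff1d(np.arange(4), idx)
        np.testing.assert_array_equal(out[untouched], X[untouched])

    def test_fixed_rng_state_reproducible(self):
        X = np.arange(30.0).reshape(10, 3)
        out1, idx1 = mask_spots(X, 0.3, np.zeros(3), np.random.default_rng(5))
        out2, idx2 = mask_spots(X, 0.3, np.zeros(3), np.random.default_rng(5))
        np.testing.assert_array_equal(idx1, idx2)
        np.testing.assert_array_equal(out1, out2)


class TestReconstructionLoss:
    def test_bounds_attained(self, rng):
        X = rng.normal(size=(5, 4)) + 3
        assert reconstruction_loss(X, X) == pytest.approx(0.0)
        assert reconstruction_loss(X, -X) == pytest.approx(2.0)
        A = np.array([[1.0, 0.0]])
        B = np.array([[0.0, 1.0]])
        assert reconstruction_loss(A, B) == pytest.approx(1.0)

    def test_zero_row_counts_as_orthogonal(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0]])
        assert reconstruction_loss(X, X) == pytest.approx(0.5)  # (0 + 1)/2

    def test_stays_in_range_on_random_input(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=(2, 6, 5))
            assert 0.0 <= reconstruction_loss(a, b) <= 2.0

    def test_autodiff_version_matches(self, rng):
        a, b = rng.normal(size=(2, 7, 5)) + 1
        lt = reconstruction_loss_t(Tensor(a), Tensor(b))
        assert float(lt.data) == pytest.approx(reconstruction_loss(a, b), abs=1e-9)


class TestTopologicalLoss:
    def test_ln2_at_zero_dot_both_signs(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert topological_loss(Z, {(0, 1)}, set()) == pytest.approx(np.log(2))
        assert topological_loss(Z, set(), {(0, 1)}) == pytest.approx(np.log(2))

    def test_strong_positive_edge_closed_form(self):
        Z = np.array([[np.sqrt(10.0), 0.0], [np.sqrt(10.0), 0.0]])
        expected = np.logaddexp(0, -10.0)  # softplus(-10) ≈ 4.54e-5
        assert topological_loss(Z, {(0, 1)}, set()) == pytest.approx(expected,
                                                                     rel=1e-9)

    def test_monotone_in_dot_product(self):
        dots = np.linspace(-5, 5, 21)
        pos_vals, neg_vals = [], []
        for d in dots:
            Z = np.array([[1.0, 0.0], [d, 0.0]])
            pos_vals.append(topological_loss(Z, {(0, 1)}, set()))
            neg_vals.append(topological_loss(Z, set(), {(0, 1)}))
        assert all(np.diff(pos_vals) < 0)
        assert all(np.diff(neg_vals) > 0)

    def test_no_overflow_at_huge_dots(self):
        Z = np.array([[100.0, 0.0], [100.0, 0.0]])  # dot = 1e4
        assert np.isfinite(topological_loss(Z, {(0, 1)}, set()))
        assert np.isfinite(topological_loss(Z, set(), {(0, 1)}))

    def test_mean_reduction_divides_by_edge_count(self, rng):
        Z = rng.normal(size=(6, 3))
        pos = {(0, 1), (2, 3), (4, 5)}
        s = topological_loss(Z, pos, set(), reduction="sum")
        m = topological_loss(Z, pos, set(), reduction="mean")
        assert m == pytest.approx(s / 3)

    def test_autodiff_version_matches(self, rng):
        Z = rng.normal(size=(8, 4))
        pos = np.array([[0, 1], [2, 3]])
        neg = np.array([[4, 5], [6, 7]])
        lt = topological_loss_t(Tensor(Z), pos, neg)
        ref = topological_loss(Z, {(0, 1), (2, 3)}, {(4, 5), (6, 7)})
        assert float(lt.data) == pytest.approx(ref, abs=1e-9)


class TestAutoencoderShapes:
    def test_masked_autoencoding_reduces_loss(self, rng):
        """With no negative edges and no clustering term the model is a
        masked graph autoencoder; a few steps should reduce the cosine error."""
        from s3rl.nn import Adam

        n, m = 30, 12
        X = np.abs(rng.normal(size=(n, m))) + 0.1
        adj = (rng.random((n, n)) < 0.15)
        adj = (adj | adj.T) & ~np.eye(n, dtype=bool)
        pairs = pairs_from_adj(adj)
        model = GTNAutoencoder(m, GTNConfig(d_hidden=16, d_latent=8), rng)
        opt = Adam(model.params, lr=1e-2)
        losses = []
        for _ in range(30):
            Z = model.encode(Tensor(X), pairs)
            out = model.decode(Z, pairs)
            loss = reconstruction_loss_t(Tensor(X), out)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        assert losses[-1] < losses[0]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="mask_ratio"):
            GTNConfig(mask_ratio=1.0)
        with pytest.raises(ValueError, match="loss_on"):
            GTNConfig(loss_on="bogus")
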