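import numpy as np
import pytest

from imcodec.ffnn import (
    NetworkWeights,
    TrainConfig,
    activation,
    activation_deriv,
    bp_update,
    decode_hidden,
    encode_blocks,
    forward,
    forward_batch,
    genome_decode,
    genome_encode,
    genome_layout,
    random_weights,
    reconstruction_loss,
    train_bp,
    train_genpso_bp,
)
from imcodec.genpso import GenPSOConfig
from imcodec.image_io import BlockSet, to_blocks


def _repeated_block_set(rng, n_rep=4, k=16):
    block = rng.uniform(0.1, 0.9, k)
    return BlockSet(np.tile(block, (n_rep, 1)), 4, 1, n_rep, 4, 4 * n_rep,
                    normalized=True)


class TestActivation:
    def test_known_values(self):
        assert activation(0.0) == pytest.approx(0.5)
        assert activation(1.0) == pytest.approx(0.7311, abs=1e-4)
        assert activation_deriv(0.5) == pytest.approx(0.25)

    def test_saturation_stays_finite(self):
        assert 0.0 < activation(-30.0) < activation(30.0) < 1.0


class TestForward:
    def test_zero_weights_give_half(self):
        wts = NetworkWeights(np.zeros((4, 3)), np.zeros(3), np.zeros((3, 4)),
                             np.zeros(4))
        tr = forward(wts, np.array([0.2, 0.4, 0.6, 0.8]))
        assert np.allclose(tr.z, 0.5) and np.allclose(tr.y, 0.5)

    def test_hand_chain_1_1_1(self):
        wts = NetworkWeights(np.ones((1, 1)), np.zeros(1), np.ones((1, 1)),
                             np.zeros(1))
        tr = forward(wts, np.array([1.0]))
        assert tr.z[0] == pytest.approx(0.7311, abs=1e-4)
        assert tr.y[0] == pytest.approx(0.6750, abs=1e-4)

    def test_bias_only_path_ignores_input(self, rng):
        wts = NetworkWeights(np.zeros((4, 2)), rng.normal(size=2),
                             rng.normal(size=(2, 4)), rng.normal(size=4))
        y1 = forward(wts, np.zeros(4)).y
        y2 = forward(wts, np.ones(4)).y
        assert np.allclose(y1, y2)

    def test_batch_matches_single(self, rng):
        wts = random_weights(6, 3, 6, rng)
        xs = rng.uniform(0, 1, (5, 6))
        z, y = forward_batch(wts, xs)
        for i in range(5):
            tr = forward(wts, xs[i])
            assert np.allclose(z[i], tr.z) and np.allclose(y[i], tr.y)

    def test_shape_mismatch(self, rng):
        wts = random_weights(4, 2, 4, rng)
        with pytest.raises(ValueError):
            forward(wts, np.zeros(5))


class TestBpUpdate:
    def test_zero_alpha_is_identity(self, rng):
        wts = random_weights(4, 3, 4, rng)
        new, _ = bp_update(wts, rng.uniform(0, 1, 4), rng.uniform(0, 1, 4), 0.0)
        assert np.array_equal(new.v_ji, wts.v_ji)
        assert np.array_equal(new.w_jk, wts.w_jk)

    def test_exact_target_gives_zero_increments(self, rng):
        wts = random_weights(4, 3, 4, rng)
        x = rng.uniform(0, 1, 4)
        t = forward(wts, x).y
        _, g = bp_update(wts, x, t, 1.0)
        assert np.allclose(g.dw_jk, 0) and np.allclose(g.dv_ij, 0)

    def test_matches_central_finite_differences(self, rng):
        """Analytic increments = -alpha * dE/dw for E = 0.5 sum (t-y)^2."""

        def loss(wts, x, t):
            return 0.5 * np.sum((forward(wts, x).y - t) ** 2)

        layout = genome_layout(4, 3, 4)
        eps = 1e-4
        for _ in range(10):
            wts = random_weights(4, 3, 4, rng)
            x = rng.uniform(0, 1, 4)
            t = rng.uniform(0, 1, 4)
            _, g = bp_update(wts, x, t, alpha=1.0)
            analytic = np.concatenate(
                [g.dv_ij.ravel(), g.dv_oj, g.dw_jk.ravel(), g.dw_ok]
            )
            genome = genome_encode(wts)
            numeric = np.empty_like(genome)
            for i in range(genome.size):
                gp, gm = genome.copy(), genome.copy()
                gp[i] += eps
                gm[i] -= eps
                numeric[i] = (
                    loss(genome_decode(gp, layout), x, t)
                    - loss(genome_decode(gm, layout), x, t)
                ) / (2 * eps)
            rel = np.linalg.norm(analytic + numeric) / np.linalg.norm(numeric)
            assert rel < 1e-6


class TestTrainBp:
    def test_tiny_step_descends(self, rng):
        bs = _repeated_block_set(rng)
        wts = random_weights(16, 8, 16, rng)
        before = reconstruction_loss(wts, bs.blocks)
        _, hist = train_bp(wts, bs, TrainConfig(alpha=1e-6, epochs=1,
                                                hidden_size=8))
        assert len(hist) == 1
        assert hist[0] <= before + 1e-9

    def test_memorizes_single_repeated_block(self, rng):
        bs = _repeated_block_set(rng)
        wts = random_weights(16, 8, 16, rng)
        _, hist = train_bp(wts, bs, TrainConfig(alpha=0.5, epochs=500,
                                                shuffle=False, hidden_size=8))
        assert hist[-1] < 0.01

    def test_deterministic_history(self, rng):
        bs = _repeated_block_set(rng)
        wts = random_weights(16, 8, 16, np.random.default_rng(0))
        cfg = TrainConfig(alpha=0.3, epochs=5, shuffle=False, seed=7,
                          hidden_size=8)
        _, h1 = train_bp(wts, bs, cfg)
        _, h2 = train_bp(wts, bs, cfg)
        assert h1 == h2

    def test_empty_blockset_rejected(self, rng):
        wts = random_weights(16, 8, 16, rng)
        bs = BlockSet(np.empty((0, 16)), 4, 0, 0, 0, 0, normalized=True)
        with pytest.raises(ValueError, match="empty"):
            train_bp(wts, bs, TrainConfig(hidden_size=8))

    def test_unnormalized_rejected(self, rng):
        wts = random_weights(16, 8, 16, rng)
        bs = BlockSet(np.zeros((2, 16), dtype=int), 4, 1, 2, 4, 8)
        with pytest.raises(ValueError, match="normalized"):
            train_bp(wts, bs, TrainConfig(hidden_size=8))


class TestGenome:
    def test_layout_length_2_2_1(self):
        assert genome_layout(2, 2, 1).length == 9  # 2*2 + 2 + 2*1 + 1

    def test_encode_decode_round_trip(self, rng):
        wts = random_weights(5, 3, 5, rng)
        layout = genome_layout(5, 3, 5)
        back = genome_decode(genome_encode(wts), layout)
        for a, b in [(wts.v_ji, back.v_ji), (wts.v_oj, back.v_oj),
                     (wts.w_jk, back.w_jk), (wts.w_ok, back.w_ok)]:
            assert np.array_equal(a, b)

    def test_hidden_node_slice_has_n_plus_1_entries(self):
        layout = genome_layout(7, 4, 7)
        for j in range(4):
            assert len(layout.node_indices[j]) == 8

    def test_node_indices_address_the_right_weights(self, rng):
        n, p, m = 3, 2, 3
        wts = random_weights(n, p, m, rng)
        genome = genome_encode(wts)
        layout = genome_layout(n, p, m)
        j = 1
        expected = np.concatenate([wts.v_ji[:, j], [wts.v_oj[j]]])
        assert np.array_equal(genome[layout.node_indices[j]], expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            genome_decode(np.zeros(5), genome_layout(2, 2, 1))


class TestTrainGenPsoBp:
    def _blocks(self, rng, n=32):
        protos = np.stack([np.full(16, 0.2), np.full(16, 0.8)])
        rows = protos[rng.integers(0, 2, n)]
        return BlockSet(rows, 4, 1, n, 4, 4 * n, normalized=True)

    def _gcfg(self, seed=0, iters=10):
        layout = genome_layout(16, 2, 16)
        return GenPSOConfig(dim=layout.length, bounds=(-1.0, 1.0), pop_size=10,
                            total_iters=iters, seed=seed)

    def test_zero_epochs_returns_evolved_weights(self, rng):
        bs = self._blocks(rng)
        wts = train_genpso_bp(bs, self._gcfg(), TrainConfig(epochs=0,
                                                            hidden_size=2))
        # rebuilding with the same seeds must give the same weights
        wts2 = train_genpso_bp(bs, self._gcfg(), TrainConfig(epochs=0,
                                                             hidden_size=2))
        assert np.array_equal(wts.v_ji, wts2.v_ji)

    def test_beats_random_weight_baseline(self, rng):
        bs = self._blocks(rng)
        trained = train_genpso_bp(bs, self._gcfg(iters=20),
                                  TrainConfig(alpha=0.5, epochs=100,
                                              hidden_size=2, seed=0))
        baseline = random_weights(16, 2, 16, np.random.default_rng(0))
        assert reconstruction_loss(trained, bs.blocks) < reconstruction_loss(
            baseline, bs.blocks
        )

    def test_dim_mismatch_rejected(self, rng):
        bs = self._blocks(rng)
        bad = GenPSOConfig(dim=4, bounds=(-1, 1), pop_size=4, total_iters=4)
        with pytest.raises(ValueError, match="genome length"):
            train_genpso_bp(bs, bad, TrainConfig(hidden_size=2))


class TestEncodeDecode:
    def test_hidden_codes_in_unit_interval(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        bs = to_blocks(img, 8, normalize=True)
        wts = random_weights(64, 16, 64, rng)
        z = encode_blocks(wts, bs)
        assert z.shape == (4, 16)
        assert np.all((z > 0) & (z < 1))

    def test_split_equals_full_forward(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        bs = to_blocks(img, 8, normalize=True)
        wts = random_weights(64, 16, 64, rng)
        z = encode_blocks(wts, bs)
        out = decode_hidden(wts, z, bs)
        _, y = forward_batch(wts, bs.blocks)
        assert np.allclose(out.blocks, y)

    def test_bottleneck_is_4x_reduction(self):
        # 64-pixel blocks squeezed to p=16 hidden units
        layout = genome_layout(64, 16, 64)
        assert layout.n // layout.p == 4


class TestWeightFiles:
    def test_save_load_round_trip(self, tmp_path, rng):
        from imcodec.ffnn import load_weights, save_weights

        wts = random_weights(8, 4, 8, rng)
        path = tmp_path / "net.weights"
        save_weights(wts, path)
        back = load_weights(path)
        assert np.array_equal(back.v_ji, wts.v_ji)
        assert np.array_equal(back.w_ok, wts.w_ok)

    def test_truncated_file_rejected(self, tmp_path):
        from imcodec.ffnn import load_weights

        path = tmp_path / "bad.weights"
        path.write_bytes(b"\x01")
        with pytest.raises(ValueError, match="truncated"):
            load_weights(path)
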