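import numpy as np
import pytest

from flow4d.enhancer import (BLOCK_SIZE, Block, TrainSchedule, augment_flip,
                             build_network, continuity_check, enhance,
                             flip_block, load_checkpoint, sample_block,
                             save_checkpoint, split_pairs, train)
from flow4d.errors import InvalidParameterError, SamplingExhaustedError
from flow4d.mriforward import AcquisitionConfig, TrainingPair
from flow4d.nn import (Adam, NetworkConfig, ResidualDenoiser,
                       magnitude_weighted_loss)


def _uniform_pair(shape=(40, 40, 40), velocity=(1.0, 0.0, 0.0)):
    truth = np.zeros((3,) + shape, dtype=np.float32)
    for c, v in enumerate(velocity):
        truth[c] = v
    return TrainingPair(truth=truth, corrupted_velocity=truth.copy(),
                        magnitude=np.ones(shape, dtype=np.float32),
                        mask_fraction=np.ones(shape, dtype=np.float32),
                        spacing=1.0, pair_id="uniform")


class TestContinuity:
    def test_uniform_flow_accepted(self):
        v = np.zeros((3, 32, 32, 32))
        v[0] = 1.0
        assert continuity_check(v)

    def test_all_zero_accepted(self):
        assert continuity_check(np.zeros((3, 32, 32, 32)))

    def test_source_rejected(self):
        # flow leaves through +x but never enters: a cap inside the block
        v = np.zeros((3, 32, 32, 32))
        v[0, 12:20, 12:20, 16:] = 1.0
        assert not continuity_check(v)

    def test_tolerance_scales(self):
        v = np.zeros((3, 32, 32, 32))
        v[0] = 1.0
        v[0, :, :, -1] *= 1.001  # 0.1% imbalance on the out-face
        assert not continuity_check(v, tolerance=1e-5)
        assert continuity_check(v, tolerance=1e-2)

    def test_flip_invariance(self):
        # flux antisymmetry: flipping axis + negating the component leaves
        # the accept/reject decision unchanged
        rng = np.random.default_rng(0)
        v = rng.normal(size=(3, 32, 32, 32)).astype(np.float32)
        block = Block(corrupted=np.concatenate([v, np.ones((1, 32, 32, 32),
                                                           dtype=np.float32)]),
                      truth=v, origin=(0, 0, 0))
        base = continuity_check(v, 1e-3)
        for flips in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]:
            flipped = flip_block(block, flips)
            assert continuity_check(flipped.truth, 1e-3) == base


class TestSampleBlock:
    def test_divergence_free_parent_first_draw(self):
        pair = _uniform_pair()
        rng = np.random.default_rng(0)
        blk = sample_block(pair, rng)
        assert blk.truth.shape == (3, 32, 32, 32)
        assert blk.pair_id == "uniform"

    def test_small_parent_rejected(self):
        pair = _uniform_pair(shape=(16, 40, 40))
        with pytest.raises(InvalidParameterError):
            sample_block(pair, np.random.default_rng(0))

    def test_seeded_determinism(self):
        pair = _uniform_pair()
        a = sample_block(pair, np.random.default_rng(3))
        b = sample_block(pair, np.random.default_rng(3))
        assert a.origin == b.origin

    def test_exhaustion_on_source_field(self):
        # a pure monopole-like source field conserves mass nowhere
        shape = (36, 36, 36)
        truth = np.zeros((3,) + shape, dtype=np.float32)
        truth[0] = np.linspace(0, 5, 36)[None, None, :]  # d(vx)/dx > 0
        pair = TrainingPair(truth=truth, corrupted_velocity=truth.copy(),
                            magnitude=np.ones(shape, dtype=np.float32),
                            mask_fraction=np.ones(shape, dtype=np.float32),
                            spacing=1.0)
        with pytest.raises(SamplingExhaustedError):
            sample_block(pair, np.random.default_rng(0), max_retries=30)


class TestFlips:
    def test_involution(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(3, 32, 32, 32)).astype(np.float32)
        m = rng.random((1, 32, 32, 32)).astype(np.float32)
        blk = Block(corrupted=np.concatenate([v, m]), truth=v.copy(),
                    origin=(0, 0, 0))
        flips = (True, False, True)
        twice = flip_block(flip_block(blk, flips), flips)
        assert np.array_equal(twice.truth, blk.truth)
        assert np.array_equal(twice.corrupted, blk.corrupted)

    def test_flip_negates_component(self):
        v = np.zeros((3, 32, 32, 32), dtype=np.float32)
        v[0] = 1.0
        m = np.ones((1, 32, 32, 32), dtype=np.float32)
        blk = Block(corrupted=np.concatenate([v, m]), truth=v.copy(),
                    origin=(0, 0, 0))
        out = flip_block(blk, (False, False, True))  # flip x
        assert np.all(out.truth[0] == -1.0)
        assert np.all(out.corrupted[0] == -1.0)
        assert np.all(out.corrupted[3] == 1.0)  # magnitude not negated

    def test_random_flip_is_valid_block(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(3, 32, 32, 32)).astype(np.float32)
        m = rng.random((1, 32, 32, 32)).astype(np.float32)
        blk = Block(corrupted=np.concatenate([v, m]), truth=v.copy(),
                    origin=(0, 0, 0))
        out = augment_flip(blk, rng)
        loss = magnitude_weighted_loss(out.corrupted[:3][None], out.truth[None],
                                       out.corrupted[3][None])
        assert np.isfinite(loss)


class TestLoss:
    def test_zero_when_equal(self):
        x = np.random.default_rng(0).normal(size=(1, 3, 8, 8, 8))
        m = np.random.default_rng(1).random((1, 8, 8, 8))
        assert magnitude_weighted_loss(x, x, m) == 0.0

    def test_uniform_weights_give_mse(self):
        rng = np.random.default_rng(2)
        p = rng.normal(size=(2, 3, 6, 6, 6))
        t = rng.normal(size=(2, 3, 6, 6, 6))
        m = np.full((2, 6, 6, 6), 0.7)
        assert magnitude_weighted_loss(p, t, m) == pytest.approx(
            np.mean((p - t) ** 2))

    def test_zero_weight_zero_loss(self):
        p = np.ones((1, 3, 4, 4, 4))
        t = np.zeros((1, 3, 4, 4, 4))
        m = np.zeros((1, 4, 4, 4))
        m[0, 0, 0, 0] = 0.0
        with pytest.warns(UserWarning):
            assert magnitude_weighted_loss(p, t, m) == 0.0

    def test_error_only_at_zero_weight(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(1, 3, 6, 6, 6))
        p = t.copy()
        m = np.ones((1, 6, 6, 6))
        m[0, 2, 2, 2] = 0.0
        p[:, :, 2, 2, 2] += 100.0
        assert magnitude_weighted_loss(p, t, m) == 0.0

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        net = ResidualDenoiser(NetworkConfig(n_residual_blocks=2, channels=8,
                                             dilations=(1, 2)),
                               seed=2, dtype=np.float64)
        for p, _ in net.params():
            p += 0.1 * rng.standard_normal(p.shape)
        x = rng.normal(size=(1, 4, 8, 8, 8))
        t = rng.normal(size=(1, 3, 8, 8, 8))
        m = rng.random((1, 8, 8, 8))

        def closure():
            return magnitude_weighted_loss(net.forward(x), t, m, return_grad=True)

        _, grad = closure()
        net.zero_grad()
        net.backward(grad)
        sel = np.random.default_rng(7)
        for p, g in net.params():
            idx = tuple(sel.integers(0, s) for s in p.shape)
            eps = 1e-6
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = closure()
            p[idx] = orig - eps
            lm, _ = closure()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-10)


class TestNetwork:
    def test_identity_at_init(self):
        net = build_network(NetworkConfig(n_residual_blocks=2, channels=8), seed=1)
        x = np.random.default_rng(0).normal(size=(2, 4, 32, 32, 32)).astype(np.float32)
        y = net.forward(x)
        assert np.array_equal(y, x[:, :3])

    def test_shape_preserved(self):
        net = build_network(NetworkConfig(n_residual_blocks=1, channels=8), seed=0)
        x = np.zeros((1, 4, 32, 32, 32), dtype=np.float32)
        assert net.forward(x).shape == (1, 3, 32, 32, 32)

    def test_parameter_count_positive(self):
        net = build_network(seed=0)
        assert net.n_parameters() > 0

    def test_checkpoint_roundtrip(self, tmp_path):
        from flow4d.enhancer import TrainState
        net = build_network(NetworkConfig(n_residual_blocks=1, channels=8), seed=3)
        rng = np.random.default_rng(0)
        for p, _ in net.params():
            p += rng.standard_normal(p.shape).astype(p.dtype)
        save_checkpoint(net, TrainState(seed=3), str(tmp_path))
        net2, state = load_checkpoint(str(tmp_path))
        x = rng.normal(size=(1, 4, 32, 32, 32)).astype(np.float32)
        assert np.array_equal(net.forward(x), net2.forward(x))
        assert state.seed == 3


class TestTraining:
    def test_split_80_20(self):
        labels = [f"f{i}" for i in range(10)]
        split = split_pairs(labels, np.random.default_rng(0))
        assert sorted(split) == sorted(labels)
        assert sum(v == "val" for v in split.values()) == 2
        assert sum(v == "train" for v in split.values()) == 8

    def test_batch_accounting(self):
        from flow4d.enhancer import BATCH_SIZE, BLOCKS_PER_SIMULATION
        assert BLOCKS_PER_SIMULATION // BATCH_SIZE == 4

    def test_toy_training_reduces_loss(self, toy_training_run):
        net, state = toy_training_run
        assert state.train_losses[-1] < state.train_losses[0]
        assert all(np.isfinite(state.train_losses))
        assert len(state.val_losses) == len(state.train_losses)

    def test_single_field_rejected(self, steady_tube_field):
        with pytest.raises(InvalidParameterError):
            train([steady_tube_field])

    def test_weight_averaged_schedule_produces_working_net(self):
        from conftest import toy_train
        net, state = toy_train(seed=11, epochs=3, swa_epochs=2)
        x = np.random.default_rng(0).normal(size=(1, 4, 32, 32, 32)).astype(np.float32)
        assert np.all(np.isfinite(net.forward(x)))
        assert len(state.train_losses) == 3

    def test_fixed_seed_reproduces_loss_curve_bitwise(self):
        from conftest import toy_train
        _, a = toy_train(seed=9, epochs=2)
        _, b = toy_train(seed=9, epochs=2)
        assert a.train_losses == b.train_losses
        assert a.val_losses == b.val_losses


class TestEnhance:
    def test_identity_network_propagates(self):
        net = build_network(NetworkConfig(n_residual_blocks=1, channels=8), seed=0)
        rng = np.random.default_rng(0)
        vel = rng.normal(size=(3, 40, 44, 40)).astype(np.float32)
        mag = rng.random((40, 44, 40)).astype(np.float32)
        out = enhance(vel, mag, net)
        assert out.shape == vel.shape
        assert np.abs(out - vel).max() < 1e-5

    def test_small_volume_padded(self):
        net = build_network(NetworkConfig(n_residual_blocks=1, channels=8), seed=0)
        vel = np.ones((3, 20, 20, 20), dtype=np.float32)
        mag = np.ones((20, 20, 20), dtype=np.float32)
        out = enhance(vel, mag, net)
        assert out.shape == (3, 20, 20, 20)
        assert np.all(np.isfinite(out))

    def test_tiling_consistency(self, toy_training_run):
        net, _ = toy_training_run
        rng = np.random.default_rng(1)
        vel = rng.normal(size=(3, 48, 48, 48)).astype(np.float32) * 10
        mag = rng.random((48, 48, 48)).astype(np.float32)
        a = enhance(vel, mag, net, tile_overlap=8)
        b = enhance(vel, mag, net, tile_overlap=16)
        rel = np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a ** 2))
        assert rel < 0.01

    def test_zero_input_finite(self):
        net = build_network(NetworkConfig(n_residual_blocks=1, channels=8), seed=0)
        out = enhance(np.zeros((3, 32, 32, 32), np.float32),
                      np.zeros((32, 32, 32), np.float32), net)
        assert np.all(np.isfinite(out))
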