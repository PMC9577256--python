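"""Architecture arithmetic, training contracts, freezing, bottleneck features."""

import numpy as np
import pytest

from nirtransfer.resnet1d import (
    ResnetConfig,
    TrainConfig,
    bottleneck_features,
    build_backbone,
    fine_tune,
    train,
)

TINY = ResnetConfig(
    n_stages=1,
    basic_blocks_per_stage=1,
    channels=(4,),
    fc_sizes=(8,),
    downsample_stride_per_stage=(2,),
)

SMALL = ResnetConfig(
    n_stages=2,
    basic_blocks_per_stage=2,
    channels=(4, 8),
    fc_sizes=(16, 8),
    downsample_stride_per_stage=(2, 2),
)


def toy_data(n=20, length=64, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, length))
    y = 0.1 * X[:, :8].sum(axis=1) + 0.6
    return X, y


class TestArchitecture:
    def test_default_config_has_16_main_convs(self):
        assert ResnetConfig().n_conv_layers == 16

    def test_default_flatten_dim_for_full_grid(self):
        """2151 points through four stride-2 stages: ceil(2151/16)=135."""
        model = build_backbone(2151, ResnetConfig())
        assert model.flatten_dim == 135 * 512
        assert len(model.conv_layers) == 16

    def test_tiny_config_builds_and_outputs_scalar(self):
        model = build_backbone(32, TINY)
        out = model.forward(np.random.default_rng(0).standard_normal((3, 32)), training=False)
        assert out.shape == (3,)

    def test_input_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_backbone(8, ResnetConfig(downsample_stride_per_stage=(4, 4, 4, 4)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ResnetConfig(n_stages=2, channels=(64,))
        with pytest.raises(ValueError):
            ResnetConfig(kernel_size=4)

    def test_zero_residual_branch_is_identity_up_to_projection(self):
        """Zeroing main-branch weights leaves only the shortcut path."""
        cfg = ResnetConfig(
            n_stages=1,
            basic_blocks_per_stage=1,
            channels=(1,),
            fc_sizes=(4,),
            downsample_stride_per_stage=(1,),
        )
        model = build_backbone(16, cfg)
        blk = model.blocks[0]
        assert blk.proj is None  # 1->1 channels, stride 1: identity shortcut
        for conv in blk.main_convs():
            conv.W.value[...] = 0.0
            conv.b.value[...] = 0.0
        blk.bn2.beta.value[...] = 0.0
        x = np.abs(np.random.default_rng(1).standard_normal((2, 1, 16)))
        out = blk.forward(x, training=False)
        # main branch contributes bn2(0)=beta=0; shortcut passes x; ReLU(x)=x
        assert np.allclose(out, x, atol=1e-12)


class TestTraining:
    def test_overfits_small_synthetic_set(self):
        X, y = toy_data()
        model = build_backbone(64, TINY)
        tc = TrainConfig(max_epochs=200, initial_lr=3e-3, early_stop_patience=50, seed=1)
        train(model, X, y, tc)
        hist = model.training_history
        assert hist[-1] < 0.1 * hist[0]

    def test_seeded_training_reproducible(self):
        X, y = toy_data()
        tc = TrainConfig(max_epochs=15, seed=3)
        m1 = train(build_backbone(64, TINY, seed=5), X, y, tc)
        m2 = train(build_backbone(64, TINY, seed=5), X, y, tc)
        assert m1.training_history == m2.training_history
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_early_stopping_on_converged_model(self):
        X, y = toy_data()
        model = build_backbone(64, TINY)
        train(model, X, y, TrainConfig(max_epochs=120, initial_lr=3e-3, seed=1))
        n_before = len(model.training_history)
        # restart training on the converged model with patience 1; full-batch
        # updates at a negligible rate leave the monitored loss flat
        train(model, X, y, TrainConfig(max_epochs=50, initial_lr=1e-9, batch_size=20, early_stop_patience=1, seed=1))
        assert len(model.training_history) - n_before <= 2

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        X, y = toy_data()
        X[0, 0] = np.inf
        model = build_backbone(64, TINY)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, X, y, TrainConfig(max_epochs=3, batch_size=20))


class TestFineTune:
    def _source(self):
        X, y = toy_data(seed=2)
        model = build_backbone(64, SMALL)
        train(model, X, y, TrainConfig(max_epochs=10, seed=2))
        return model, X, y

    def test_freeze_all_convs_bit_identical(self):
        src, X, y = self._source()
        weights = src.get_weights()
        total = len(src.conv_layers)
        tgt = build_backbone(64, SMALL, seed=9)
        fine_tune(tgt, weights, total, X + 0.1, y + 0.05, TrainConfig(max_epochs=10, seed=9))
        for i, conv in enumerate(tgt.conv_layers):
            src_conv = src.conv_layers[i]
            assert np.array_equal(conv.W.value, src_conv.W.value)
            assert np.array_equal(conv.b.value, src_conv.b.value)

    def test_unfrozen_convs_change(self):
        src, X, y = self._source()
        weights = src.get_weights()
        tgt = build_backbone(64, SMALL, seed=9)
        fine_tune(tgt, weights, 0, X + 0.1, y + 0.05, TrainConfig(max_epochs=10, seed=9))
        changed = [
            not np.array_equal(c.W.value, s.W.value)
            for c, s in zip(tgt.conv_layers, src.conv_layers)
        ]
        assert all(changed)

    def test_partial_freeze_mask(self):
        """Freezing L=4 of 8 convs freezes exactly the first four."""
        src, X, y = self._source()
        tgt = build_backbone(64, SMALL, seed=9)
        fine_tune(tgt, src.get_weights(), 4, X, y, TrainConfig(max_epochs=5, seed=9))
        assert tgt.freeze_mask == [True] * 4 + [False] * 4

    def test_shape_mismatch_lists_offenders(self):
        src, X, y = self._source()
        tgt = build_backbone(64, TINY)
        with pytest.raises(ValueError, match="mismatch"):
            tgt.set_weights(src.get_weights())


class TestBottleneck:
    def test_identical_inputs_identical_features(self):
        model = build_backbone(64, TINY)
        x = np.random.default_rng(0).standard_normal(64)
        feats = bottleneck_features(model, np.stack([x, x]))
        assert np.array_equal(feats[0], feats[1])

    def test_shape_contract(self):
        model = build_backbone(64, SMALL)
        feats = bottleneck_features(model, np.zeros((7, 64)))
        assert feats.shape == (7, model.flatten_dim)

    def test_repeat_calls_bit_identical(self):
        X, y = toy_data()
        model = build_backbone(64, TINY)
        train(model, X, y, TrainConfig(max_epochs=5, seed=0))
        f1 = bottleneck_features(model, X)
        f2 = bottleneck_features(model, X)
        assert np.array_equal(f1, f2)

    def test_wrong_input_length_rejected(self):
        model = build_backbone(64, TINY)
        with pytest.raises(ValueError, match="length"):
            bottleneck_features(model, np.zeros((2, 63)))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = toy_data()
        model = build_backbone(64, TINY)
        train(model, X, y, TrainConfig(max_epochs=5, seed=0))
        model.save(tmp_path / "ckpt")
        loaded = type(model).load(tmp_path / "ckpt")
        assert np.array_equal(model.predict(X), loaded.predict(X))
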