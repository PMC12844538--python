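"""Fusion regressor: architecture contracts, parameter counts, fusion algebra."""

import numpy as np
import pytest

from emofuse import (
    FusionModel,
    FusionModelConfig,
    InvalidInputError,
    build_ablation_model,
    build_cnn_branch,
    build_mlp_branch,
    fuse,
)
from emofuse import nn
from emofuse.errors import ShapeError


def cnn_param_count(c_in: int, length: int) -> int:
    """Independent layer-by-layer hand count of the default CNN branch."""
    conv1 = 8 * c_in * 9 + 8
    dw1 = 8 * 2 * 32 + 16
    dw2 = 16 * 1 * 26 + 16
    pw = 16 * 16 * 1 + 16
    dense1 = (16 * (length // 4)) * 200 + 200
    dense2 = 200 * 2 + 2
    return conv1 + dw1 + dw2 + pw + dense1 + dense2


def mlp_param_count(d: int) -> int:
    return (d * 1000 + 1000) + (1000 * 1000 + 1000) + (1000 * 2 + 2)


def zero_weights(module, final_bias=(0.0, 0.0)):
    for _, layer, pname in module.named_parameters():
        layer.parameters()[pname][...] = 0.0
    last = module.layers[-1]
    last.b[...] = np.asarray(final_bias, dtype=last.b.dtype)


@pytest.fixture
def config():
    return FusionModelConfig()


class TestBranches:
    def test_cnn_branch_output_is_two_reals(self, config, rng):
        branch = build_cnn_branch(config, 32, 300, rng)
        y = branch.forward(np.random.default_rng(0).standard_normal((3, 32, 300)).astype(np.float32))
        assert y.shape == (3, 2)

    def test_cnn_zero_weights_pass_final_bias_through(self, config, rng):
        branch = build_cnn_branch(config, 4, 100, rng, np.float64)
        zero_weights(branch, (1.5, -2.5))
        y = branch.forward(np.random.default_rng(1).standard_normal((2, 4, 100)))
        np.testing.assert_allclose(y, [[1.5, -2.5]] * 2)

    @pytest.mark.parametrize("c_in,length", [(1, 256), (32, 90), (8, 500)])
    def test_cnn_parameter_count_matches_hand_arithmetic(self, config, rng, c_in, length):
        branch = build_cnn_branch(config, c_in, length, rng)
        assert branch.n_parameters() == cnn_param_count(c_in, length)

    def test_cnn_too_short_input_names_minimum(self, config, rng):
        with pytest.raises(InvalidInputError, match="at least 32"):
            build_cnn_branch(config, 1, 10, rng)

    def test_mlp_zero_weights_pass_final_bias_through(self, config, rng):
        mlp = build_mlp_branch(config, rng, input_dim=20, dtype=np.float64)
        zero_weights(mlp, (3.0, 4.0))
        y = mlp.forward(np.zeros((2, 20)))
        np.testing.assert_allclose(y, [[3.0, 4.0]] * 2)

    @pytest.mark.parametrize("d", [910, 1278, 590])
    def test_mlp_parameter_count_matches_hand_arithmetic(self, config, rng, d):
        mlp = build_mlp_branch(config, rng, input_dim=d)
        assert mlp.n_parameters() == mlp_param_count(d)

    def test_mlp_output_always_length_two(self, config, rng):
        mlp = build_mlp_branch(config, rng, input_dim=17)
        assert mlp.forward(np.zeros((5, 17), dtype=np.float32)).shape == (5, 2)

    def test_mlp_input_length_mismatch_raises(self, config, rng):
        mlp = build_mlp_branch(config, rng, input_dim=17)
        with pytest.raises(ShapeError):
            mlp.forward(np.zeros((5, 16), dtype=np.float32))

    def test_default_mlp_input_dim_is_composed_feature_length(self, config):
        # 118 windows x 5 timbre features + 32 channels x 5 bands x 2
        assert config.resolved_mlp_input_dim() == 590 + 320
        assert config.resolved_mlp_input_dim(with_eeg=False) == 590

    def test_explicit_mlp_input_dim_override(self):
        cfg = FusionModelConfig(mlp_input_dim=1278)
        assert cfg.resolved_mlp_input_dim() == 1278


class TestFuse:
    def test_elementwise_sum(self):
        p = fuse((1, 1), (2, 2), (3, 3))
        assert (p.valence, p.arousal) == (6, 6)

    def test_additive_identity(self):
        p = fuse((2.5, 7.0), (0, 0), (0, 0))
        assert (p.valence, p.arousal) == (2.5, 7.0)

    def test_clip_mode_clamps_to_rating_scale(self):
        p = fuse((12, 0.5), (0, 0), None, clip=True)
        assert (p.valence, p.arousal) == (9.0, 1.0)

    def test_non_finite_branch_named_in_error(self):
        with pytest.raises(InvalidInputError, match="cnn_audio"):
            fuse((1, 1), (np.nan, 0), (0, 0))

    def test_wrong_length_rejected(self):
        with pytest.raises(ShapeError):
            fuse((1, 1, 1), (0, 0), (0, 0))


class TestFusionModel:
    def make_inputs(self, model, n=3, seed=0):
        r = np.random.default_rng(seed)
        feats = r.standard_normal((n, model.mlp_input_dim)).astype(np.float32)
        audio = r.standard_normal((n, model.audio_len)).astype(np.float32)
        psd = r.standard_normal((n, model.config.eeg_channels, model.eeg_len or 1)).astype(np.float32)
        return feats, audio, psd

    def test_forward_deterministic_in_eval_mode(self, config):
        model = FusionModel(config, audio_len=200, eeg_len=90, seed=5)
        feats, audio, psd = self.make_inputs(model)
        y1 = model.forward(feats, audio, psd)
        y2 = model.forward(feats, audio, psd)
        np.testing.assert_array_equal(y1, y2)

    def test_same_seed_same_initial_weights(self, config):
        m1 = FusionModel(config, audio_len=200, eeg_len=90, seed=9)
        m2 = FusionModel(config, audio_len=200, eeg_len=90, seed=9)
        for k, v in m1.state_dict().items():
            np.testing.assert_array_equal(v, m2.state_dict()[k])

    def test_total_parameter_count_is_sum_of_branches(self, config):
        model = FusionModel(config, audio_len=200, eeg_len=90, seed=0)
        expected = (
            mlp_param_count(910) + cnn_param_count(1, 200) + cnn_param_count(32, 90)
        )
        assert model.n_parameters() == expected

    def test_fusion_additivity_bias_shift(self, config):
        """Shifting one branch's final bias by delta shifts the output by delta."""
        model = FusionModel(config, audio_len=200, eeg_len=90, seed=2)
        feats, audio, psd = self.make_inputs(model)
        y0 = model.forward(feats, audio, psd)
        delta = np.array([0.75, -1.25], dtype=np.float32)
        model.audio_cnn.layers[-1].b += delta
        y1 = model.forward(feats, audio, psd)
        np.testing.assert_allclose(y1 - y0, np.tile(delta, (3, 1)), atol=1e-5)

    def test_gradient_flow_to_every_tensor(self, config):
        """After one warm-up update (the CNN output layers fade in from zero),
        every trainable tensor in every branch receives a nonzero MAE gradient."""
        model = FusionModel(config, audio_len=200, eeg_len=90, seed=3)
        model.set_dropout_rng(np.random.default_rng(0))
        feats, audio, psd = self.make_inputs(model, n=8)
        y = np.random.default_rng(1).uniform(1, 9, (8, 2))
        optimizer = nn.Adam(model.modules(), lr=1e-3)
        for _ in range(2):
            pred = model.forward(feats, audio, psd, train=True)
            model.backward(np.sign(pred - y) / pred.size)
            optimizer.step()
        for _, module in model.branches():
            for name, layer, pname in module.named_parameters():
                assert np.any(layer.gradients()[pname] != 0), name

    def test_checkpoint_round_trip(self, config, tmp_path):
        model = FusionModel(config, audio_len=200, eeg_len=90, seed=4)
        feats, audio, psd = self.make_inputs(model)
        y0 = model.forward(feats, audio, psd)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = FusionModel.load(path)
        np.testing.assert_array_equal(loaded.forward(feats, audio, psd), y0)
        assert loaded.config == model.config


class TestAblationModel:
    def test_no_eeg_parameters_and_output_ignores_eeg(self, config):
        model = build_ablation_model(config, audio_len=200, seed=6)
        assert model.eeg_cnn is None
        assert model.mlp_input_dim == 590
        r = np.random.default_rng(0)
        feats = r.standard_normal((4, 590)).astype(np.float32)
        audio = r.standard_normal((4, 200)).astype(np.float32)
        y1 = model.forward(feats, audio, r.standard_normal((4, 32, 90)))
        y2 = model.forward(feats, audio, r.standard_normal((4, 32, 90)))
        y3 = model.forward(feats, audio, None)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(y1, y3)
        assert y1.shape == (4, 2)

    def test_parameter_count_is_full_minus_eeg_branch(self, config):
        full = FusionModel(config, audio_len=200, eeg_len=90, seed=0)
        ablation = build_ablation_model(config, audio_len=200, seed=0)
        eeg_branch = cnn_param_count(32, 90)
        mlp_diff = mlp_param_count(910) - mlp_param_count(590)
        assert full.n_parameters() - ablation.n_parameters() == eeg_branch + mlp_diff


class TestConfigValidation:
    def test_output_dim_must_be_two(self):
        with pytest.raises(InvalidInputError):
            FusionModelConfig(output_dim=3)

    def test_depthwise_width_must_divide(self):
        with pytest.raises(InvalidInputError):
            FusionModelConfig(cnn_block1={"conv_filters": 8, "dw_filters": 15})

    def test_dropout_range(self):
        with pytest.raises(InvalidInputError):
            FusionModelConfig(cnn_block1={"dropout": 1.0})
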