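import numpy as np
import pytest

from conefinder.nn.layers import Conv2d, ConvTranspose2x2, BatchNorm2d, MaxPool2x2
from conefinder.nn.train import (
    TrainConfig,
    load_model,
    predict_prob_map,
    save_model,
    train_model,
)
from conefinder.nn.unet import NetworkConfig, build_unet, softmax_channels
from conefinder.experiment import synthetic_samples


def conv_params(c_in, c_out, k):
    return c_out * c_in * k * k + c_out


class TestNetworkConfig:
    def test_size_parity_constraint(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=4, in_size=100)  # 100 not divisible by 16

    def test_bottleneck_spatial_size(self):
        cfg = NetworkConfig(depth=4, in_size=144)
        assert cfg.in_size // 2**cfg.depth == 9


class TestBuildUnet:
    def test_output_shape_and_softmax_normalization(self, rng):
        cfg = NetworkConfig(depth=2, base_filters=4, kernel=3, in_size=16)
        net = build_unet(cfg, seed=0)
        x = rng.random((2, 1, 16, 16))
        probs = net.predict_probs(x)
        assert probs.shape == (2, 2, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_parameter_count_matches_hand_tally(self):
        # independent layer-by-layer arithmetic for depth=2, base=8, k=3
        cfg = NetworkConfig(depth=2, base_filters=8, kernel=3, in_size=64)
        net = build_unet(cfg, seed=0)
        expect = (
            conv_params(1, 8, 3) + 2 * 8          # encoder level 0 + BN
            + conv_params(8, 16, 3) + 2 * 16      # encoder level 1 + BN
            + conv_params(16, 32, 3) + 2 * 32     # bottleneck + BN
            + (32 * 16 * 4 + 16)                  # up-conv to level 1
            + conv_params(32, 16, 3) + 2 * 16     # decoder level 1 + BN
            + (16 * 8 * 4 + 8)                    # up-conv to level 0
            + conv_params(16, 8, 3) + 2 * 8       # decoder level 0 + BN
            + conv_params(8, 2, 1)                # 1x1 two-class head
        )
        assert net.n_parameters() == expect

    @pytest.mark.parametrize("depth,size", [(1, 8), (2, 16), (3, 24)])
    def test_size_parity_for_valid_configs(self, depth, size, rng):
        cfg = NetworkConfig(depth=depth, base_filters=2, kernel=3, in_size=size)
        net = build_unet(cfg, seed=1)
        out = net.forward(rng.random((1, 1, size, size)))
        assert out.shape == (1, 2, size, size)


class TestLayersAgainstScipy:
    def test_conv_matches_scipy_correlate(self, rng):
        from scipy import ndimage

        conv = Conv2d(1, 1, 3, np.random.default_rng(0))
        x = rng.random((1, 1, 10, 10))
        out = conv.forward(x, train=False)
        expect = ndimage.correlate(x[0, 0], conv.W[0, 0], mode="constant") + conv.b[0]
        np.testing.assert_allclose(out[0, 0], expect, atol=1e-12)

    def test_maxpool_matches_block_reduce(self, rng):
        from skimage.measure import block_reduce

        x = rng.random((1, 1, 8, 8))
        out = MaxPool2x2().forward(x, train=False)
        np.testing.assert_array_equal(out[0, 0], block_reduce(x[0, 0], (2, 2), np.max))

    def test_transposed_conv_upsamples_2x(self, rng):
        up = ConvTranspose2x2(3, 2, np.random.default_rng(0))
        out = up.forward(rng.random((1, 3, 5, 5)), train=False)
        assert out.shape == (1, 2, 10, 10)

    def test_batchnorm_normalizes_batch(self, rng):
        bn = BatchNorm2d(2)
        x = rng.random((4, 2, 6, 6)) * 10 + 3
        out = bn.forward(x, train=True)
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-7)
        np.testing.assert_allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)


class TestTraining:
    def test_one_epoch_one_sample_log_bookkeeping(self, tiny_net_cfg, tiny_mosaic):
        samples = synthetic_samples(1, tiny_mosaic, label_radius=2, seed=5)
        model = train_model(tiny_net_cfg, samples, TrainConfig(epochs=1, seed=0))
        assert len(model.training_log) == 1

    def test_same_seed_bitwise_identical_log(self, tiny_net_cfg, tiny_mosaic):
        samples = synthetic_samples(4, tiny_mosaic, label_radius=2, seed=5)
        tcfg = TrainConfig(epochs=2, seed=9)
        a = train_model(tiny_net_cfg, samples, tcfg)
        b = train_model(tiny_net_cfg, samples, tcfg)
        assert a.training_log == b.training_log

    def test_loss_decreases_on_learnable_data(self, tiny_trained_model):
        model, _ = tiny_trained_model
        assert model.training_log[-1] < model.training_log[0]

    def test_empty_dataset_rejected(self, tiny_net_cfg):
        with pytest.raises(ValueError):
            train_model(tiny_net_cfg, [], TrainConfig(epochs=1))

    def test_shape_mismatch_rejected(self, tiny_net_cfg, tiny_mosaic):
        samples = synthetic_samples(1, tiny_mosaic, label_radius=2, seed=5)
        bad_cfg = NetworkConfig(depth=2, base_filters=4, kernel=3, in_size=64)
        with pytest.raises(ValueError, match="shape"):
            train_model(bad_cfg, samples, TrainConfig(epochs=1))


class TestPrediction:
    def test_output_in_unit_interval(self, tiny_trained_model):
        model, samples = tiny_trained_model
        prob = predict_prob_map(model, samples[0].image)
        assert prob.shape == samples[0].image.shape
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_inference_is_pure(self, tiny_trained_model):
        model, samples = tiny_trained_model
        a = predict_prob_map(model, samples[0].image)
        b = predict_prob_map(model, samples[0].image)
        np.testing.assert_array_equal(a, b)

    def test_unnormalized_input_rejected(self, tiny_trained_model):
        model, _ = tiny_trained_model
        with pytest.raises(ValueError, match="normalized"):
            predict_prob_map(model, np.full((32, 32), 200.0))

    def test_probability_peaks_near_cones(self, tiny_trained_model):
        # trained on synthetic mosaics: the map maximum should sit within
        # 2 px of some truth cone
        model, samples = tiny_trained_model
        prob = predict_prob_map(model, samples[0].image)
        r, c = np.unravel_index(prob.argmax(), prob.shape)
        d = np.linalg.norm(samples[0].cones - np.array([c, r]), axis=1).min()
        assert d <= 2.0


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_trained_model, tmp_path):
        model, samples = tiny_trained_model
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.training_log == model.training_log
        np.testing.assert_array_equal(
            predict_prob_map(loaded, samples[0].image),
            predict_prob_map(model, samples[0].image),
        )
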