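"""Architecture contracts and training behavior of the classifiers."""

import numpy as np
import pytest

from cxrcad import ModelConfig, TrainConfig, build_baseline, build_custom_cnn, train_classifier
from cxrcad._nn import BatchNorm2d, Conv2d, Dropout, Linear
from cxrcad.errors import GeometryError, ValidationError


def independent_parameter_count(config: ModelConfig) -> int:
    """Layer-by-layer arithmetic oracle, written before the builder:
    conv k^2*c_in*c_out + c_out; BN 2*c_out; FC in*out + out."""
    total, c_in, size = 0, 1, config.input_size
    for c_out in config.block_filters:
        total += config.kernel**2 * c_in * c_out + c_out  # conv
        total += 2 * c_out  # BN gamma/beta
        c_in = c_out
        size = -(-size // config.block_stride)
    size //= 2  # the 2x2 average pool
    flat = size * size * c_in
    total += flat * config.fusion_width + config.fusion_width
    total += config.fusion_width * config.n_classes + config.n_classes
    return total


class TestCustomCnn:
    def test_softmax_rows_on_zero_input(self):
        spec = build_custom_cnn()
        probs = spec.predict(np.zeros((2, 256, 256)))
        assert probs.shape == (2, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_conv_spatial_size_chain(self):
        spec = build_custom_cnn()
        conv_sizes = [li.output_shape[1] for li in spec.layers if li.kind == "Conv2d"]
        assert conv_sizes == [128, 64, 32, 16, 8]
        pooled = [li for li in spec.layers if li.kind == "AvgPool2d"][0]
        assert pooled.output_shape[1:] == (4, 4)

    @pytest.mark.parametrize(
        "config",
        [ModelConfig(), ModelConfig(input_size=64, block_filters=(8, 16, 16, 16, 16))],
    )
    def test_parameter_count_matches_arithmetic_oracle(self, config):
        assert build_custom_cnn(config).total_parameters == independent_parameter_count(config)

    def test_sixteen_counted_layers(self):
        spec = build_custom_cnn()
        assert spec.counted_layers == 16  # 5 conv + 5 BN + 5 dropout + 1 FC

    def test_block_structure(self):
        spec = build_custom_cnn()
        kinds = [li.kind for li in spec.layers]
        # five Conv/ReLU/BN/Dropout blocks, then pool/flatten/fusion/head/softmax
        assert kinds[:4] == ["Conv2d", "ReLU", "BatchNorm2d", "Dropout"]
        assert kinds.count("Conv2d") == 5 and kinds.count("Dropout") == 5
        assert kinds[-1] == "Softmax"

    def test_indivisible_input_size_names_failing_layer(self):
        # 96 -> 48 -> 24 -> 12 -> 6 -> 3: the final 3x3 map cannot be 2x2-pooled
        with pytest.raises(GeometryError, match="AvgPool2d"):
            build_custom_cnn(ModelConfig(input_size=96))

    def test_inference_deterministic_dropout_inactive(self, rng):
        spec = build_custom_cnn(ModelConfig(input_size=64, block_filters=(8, 16, 16, 16, 16)))
        x = rng.random((3, 64, 64))
        assert np.array_equal(spec.predict(x), spec.predict(x))

    def test_batchnorm_uses_batch_stats_only_in_train_mode(self, rng):
        spec = build_custom_cnn(ModelConfig(input_size=64, block_filters=(8, 16, 16, 16, 16)))
        x = (rng.random((4, 1, 64, 64)) * 0.2 + 0.8).astype(np.float32)  # skewed batch
        out_eval = spec.network.forward(x, train=False)
        out_train = spec.network.forward(x, train=True, rng=np.random.default_rng(0))
        assert not np.allclose(out_eval, out_train)


class TestBaselines:
    def test_alexnet_layer_composition(self):
        spec = build_baseline("alexnet", input_size=64)
        convs = sum(isinstance(l, Conv2d) for l in spec.network.walk())
        fcs = sum(isinstance(l, Linear) for l in spec.network.walk())
        assert (convs, fcs) == (5, 3)
        assert spec.counted_layers == 8

    def test_resnet34_weighted_layer_count(self):
        spec = build_baseline("resnet34", input_size=64)
        assert spec.counted_layers == 34
        # convention: stem conv + 2 convs per basic block + final FC;
        # 1x1 downsample shortcuts are excluded
        convs = sum(isinstance(l, Conv2d) for l in spec.network.walk())
        downsamples = 3  # one per channel-doubling stage
        fcs = sum(isinstance(l, Linear) for l in spec.network.walk())
        assert convs - downsamples + fcs == 34

    def test_googlenet_depth_convention(self):
        assert build_baseline("googlenet", input_size=64).counted_layers == 22

    @pytest.mark.parametrize("name", ["alexnet", "googlenet", "resnet34"])
    def test_softmax_contract_on_zero_input(self, name):
        spec = build_baseline(name, input_size=64)
        probs = spec.predict(np.zeros((1, 64, 64)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_unknown_name_lists_valid_options(self):
        with pytest.raises(ValidationError, match="alexnet"):
            build_baseline("vgg16")


class TestTraining:
    def _tiny(self):
        return build_custom_cnn(
            ModelConfig(input_size=64, block_filters=(8, 16, 16, 16, 16), dropout_rate=0.2)
        )

    def test_separable_constant_patches_reach_perfect_accuracy(self, rng):
        x = np.concatenate([np.full((8, 64, 64), 0.1), np.full((8, 64, 64), 0.9)])
        x += rng.normal(0, 0.01, x.shape)
        y = ["normal"] * 8 + ["cancer"] * 8
        model, history = train_classifier(self._tiny(), x, y, TrainConfig(epochs=30, seed=0))
        probs = model.predict(x)
        assert ((probs[:, 1] >= 0.5) == (np.array(y) == "cancer")).all()
        assert history[-1]["acc"] == 1.0

    def test_training_is_deterministic_given_seed(self, rng):
        x = rng.random((12, 64, 64))
        y = ["cancer", "normal"] * 6
        hist1 = train_classifier(self._tiny(), x, y, TrainConfig(epochs=3, seed=5))[1]
        hist2 = train_classifier(self._tiny(), x, y, TrainConfig(epochs=3, seed=5))[1]
        assert hist1[-1]["loss"] == hist2[-1]["loss"]

    def test_single_class_data_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_classifier(self._tiny(), rng.random((4, 64, 64)), ["cancer"] * 4)

    def test_history_records_every_epoch(self, rng):
        x = rng.random((8, 64, 64))
        y = ["cancer", "normal"] * 4
        _, history = train_classifier(self._tiny(), x, y, TrainConfig(epochs=4, seed=0))
        assert [h["epoch"] for h in history] == [1, 2, 3, 4]
        assert all("loss" in h and "acc" in h for h in history)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        from cxrcad.model_zoo import load_model, save_model

        model = self._tiny()
        x = rng.random((4, 64, 64))
        y = ["cancer", "normal"] * 2
        model, _ = train_classifier(model, x, y, TrainConfig(epochs=2, seed=0))
        save_model(model, tmp_path / "ckpt.npz")
        restored = load_model(tmp_path / "ckpt.npz")
        assert np.array_equal(model.predict(x), restored.predict(x))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """End-to-end gradient check of the layer stack used by the
        custom CNN (edge-padded stride-2 conv, BN, pooling, linear)."""
        from cxrcad import _nn
        from cxrcad._nn import AvgPool2d, Flatten, ReLU, Sequential

        net = Sequential([
            Conv2d(1, 4, 2, stride=2, padding="ceil", pad_mode="edge", rng=rng),  # 9 -> 5
            ReLU(),
            BatchNorm2d(4),
            Conv2d(4, 4, 2, stride=2, padding="ceil", pad_mode="edge", rng=rng),  # 5 -> 3
            Conv2d(4, 4, 2, stride=2, padding="ceil", pad_mode="edge", rng=rng),  # 3 -> 2
            AvgPool2d(2),
            Flatten(),
            Linear(4, 2, rng=rng),
        ])
        for layer in net.walk():
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float64)
                layer.grads[k] = layer.grads[k].astype(np.float64)
        x = rng.random((3, 1, 9, 9))  # odd size exercises the edge padding
        y = np.array([0, 1, 0])

        _, d = _nn.softmax_cross_entropy(net.forward(x, train=True), y)
        net.backward(d)
        eps = 1e-3
        for layer in net.walk():
            for key, p in layer.params.items():
                idx = tuple(rng.integers(s) for s in p.shape)
                analytic = layer.grads[key][idx]
                orig = p[idx]
                p[idx] = orig + eps
                up, _ = _nn.softmax_cross_entropy(net.forward(x, train=True), y)
                p[idx] = orig - eps
                down, _ = _nn.softmax_cross_entropy(net.forward(x, train=True), y)
                p[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-7)
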