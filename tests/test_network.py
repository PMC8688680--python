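import numpy as np
import pytest

from dexaseg.network import (
    NetworkSpec,
    ResidualUnit,
    SegNet,
    audit_architecture,
    build_resblock,
    build_segmenter,
    build_unet_baseline,
    segment_image,
)


@pytest.fixture(scope="module")
def small_model():
    return build_segmenter(NetworkSpec(base_channels=4), seed=0)


class TestSpec:
    def test_channel_doubling(self):
        assert NetworkSpec().encoder_channels == (32, 64, 128, 256, 512)
        assert NetworkSpec(base_channels=8).encoder_channels == (8, 16, 32, 64, 128)

    def test_invalid(self):
        with pytest.raises(ValueError):
            NetworkSpec(base_channels=0)


class TestAudit:
    def test_proposed_census(self):
        report = audit_architecture(build_segmenter(NetworkSpec(base_channels=8)))
        d = report.to_dict()
        assert d["resblocks"] == 5
        assert d["maxpools"] == 4
        assert d["convblocks_decoder"] == 4
        assert d["transconvs"] == 4
        assert d["skip_connections"] == 4
        assert d["conv3x3_per_resblock"] == 4
        assert d["conv1x1_per_resblock"] == 2

    def test_head_channels_track_base(self):
        default = audit_architecture(build_segmenter(NetworkSpec()))
        assert default.head_in_channels == 32
        assert default.head_out_channels == 3
        toy = audit_architecture(build_segmenter(NetworkSpec(base_channels=8)))
        assert toy.head_in_channels == 8

    def test_baseline_has_convblock_encoder(self):
        report = audit_architecture(build_unet_baseline(NetworkSpec(base_channels=8)))
        assert report.resblocks == 0
        assert report.convblocks_encoder == 5
        assert report.convblocks_decoder == 4

    def test_baseline_smaller_than_proposed(self):
        spec = NetworkSpec(base_channels=8)
        res = audit_architecture(build_segmenter(spec)).n_parameters
        base = audit_architecture(build_unet_baseline(spec)).n_parameters
        assert base < res

    def test_default_baseline_first_stage_filters(self):
        model = build_unet_baseline(NetworkSpec())
        assert model.encoder_blocks[0].out_ch == 32

    def test_foreign_object_rejected(self):
        with pytest.raises(TypeError):
            audit_architecture(object())

    def test_stable_across_rebuilds(self):
        a = audit_architecture(build_segmenter(NetworkSpec(base_channels=4)))
        b = audit_architecture(build_segmenter(NetworkSpec(base_channels=4)))
        assert a == b


class TestResblock:
    def test_conv_census_and_shape(self, rng):
        block = build_resblock(3, 8, seed=1)
        x = rng.random((1, 3, 16, 16)).astype(np.float32)
        assert block.forward(x).shape == (1, 8, 16, 16)

    def test_invalid_channels(self):
        with pytest.raises(ValueError):
            build_resblock(0, 8)

    def test_residual_wiring_zeroed_main_path(self, rng):
        # zero the main-path convs: output must equal ReLU(shortcut path)
        unit = ResidualUnit(3, 5, np.random.default_rng(2))
        unit.conv1.weight.data[...] = 0
        unit.conv1.bias.data[...] = 0
        unit.conv2.weight.data[...] = 0
        unit.conv2.bias.data[...] = 0
        x = rng.random((2, 3, 8, 8)).astype(np.float32)
        out = unit.forward(x, train=False)
        # eval-mode BN with fresh running stats is the identity
        shortcut = unit.conv_sc.forward(x, train=False)
        assert np.allclose(out, np.maximum(shortcut, 0.0), atol=1e-6)


class TestForward:
    def test_softmax_probabilities(self, small_model, rng):
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        p = small_model.forward(x, train=False)
        assert p.shape == (1, 3, 64, 64)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert p.min() >= 0.0

    def test_indivisible_input_rejected(self, small_model):
        with pytest.raises(ValueError, match="divisible"):
            small_model.forward(np.zeros((1, 1, 60, 64), dtype=np.float32))

    def test_eval_forward_deterministic(self, small_model, rng):
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        assert np.array_equal(small_model.forward(x), small_model.forward(x))


class TestSegmentImage:
    def test_padding_round_trip(self, small_model, rng):
        labels = segment_image(small_model, rng.random((100, 100)).astype(np.float32))
        assert labels.shape == (100, 100)
        assert set(np.unique(labels)) <= {0, 1, 2}

    def test_probmap_consistent_with_labels(self, small_model, rng):
        labels, probs = segment_image(small_model, rng.random((48, 48)).astype(np.float32),
                                      return_probs=True)
        assert probs.shape == (3, 48, 48)
        assert np.array_equal(probs.argmax(axis=0), labels)

    def test_empty_image_rejected(self, small_model):
        with pytest.raises(ValueError):
            segment_image(small_model, np.zeros((0, 0)))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        spec = NetworkSpec(base_channels=2)
        a = SegNet(spec, seed=1)
        b = SegNet(spec, seed=2)
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        assert not np.allclose(a.forward(x), b.forward(x))
        a.save(tmp_path / "ckpt.npz")
        b.load(tmp_path / "ckpt.npz")
        assert np.array_equal(a.forward(x), b.forward(x))
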