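"""Encoders, decoders, assembled models and parameter accounting."""

import numpy as np
import pytest

from onnseg.autograd import Tensor
from onnseg.decoders import UnetDecoder
from onnseg.model_zoo import (
    DecoderSpec,
    EncoderSpec,
    SegmentationModelSpec,
    build_decoder,
    build_encoder,
    build_model,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    selfonn_unet_decoder_parameter_count,
    spec_from_yaml,
    spec_to_yaml,
)


class TestEncoders:
    def test_resnet18_stage_shapes_and_channels(self, rng):
        enc = build_encoder(EncoderSpec(family="resnet18")).eval()
        feats = enc(Tensor(rng.standard_normal((1, 3, 224, 224))))
        shapes = [f.data.shape for f in feats]
        assert shapes == [(1, 64, 112, 112), (1, 64, 56, 56), (1, 128, 28, 28),
                          (1, 256, 14, 14), (1, 512, 7, 7)]

    def test_densenet201_stage_channels(self, rng):
        enc = build_encoder(EncoderSpec(family="densenet201")).eval()
        feats = enc(Tensor(rng.standard_normal((1, 3, 64, 64))))
        assert [f.data.shape[1] for f in feats] == [64, 256, 512, 1792, 1920]

    def test_tiny_encoder_under_100k_parameters(self, rng):
        enc = build_encoder(EncoderSpec(family="tiny", in_channels=1))
        assert count_parameters(enc) < 100_000
        feats = enc(Tensor(rng.standard_normal((2, 1, 64, 64))))
        assert [f.data.shape[2] for f in feats] == [32, 16, 8, 4, 2]

    def test_rejects_indivisible_input(self, rng):
        enc = build_encoder(EncoderSpec(family="tiny", in_channels=3))
        with pytest.raises(ValueError, match="divisible"):
            enc(Tensor(rng.standard_normal((1, 3, 100, 100))))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown encoder family"):
            EncoderSpec(family="resnet19")

    def test_pretrained_without_local_weights_errors(self):
        with pytest.raises(FileNotFoundError, match="download"):
            build_encoder(EncoderSpec(family="resnet18", pretrained=True))


class TestDecoders:
    @pytest.mark.parametrize("kind", ["unet", "unetpp", "fpn", "selfonn_unet"])
    def test_output_at_input_resolution(self, rng, kind):
        espec = EncoderSpec(family="tiny", in_channels=1)
        enc = build_encoder(espec)
        dec = build_decoder(DecoderSpec(kind=kind, decoder_channels=(16, 12, 8, 8, 8)), espec)
        out = dec(enc(Tensor(rng.standard_normal((1, 1, 64, 64)))))
        assert out.data.shape[2:] == (64, 64)
        assert out.data.shape[1] == dec.out_channels

    def test_fpn_merged_channels_match_spec(self):
        espec = EncoderSpec(family="tiny", in_channels=1)
        dec = build_decoder(DecoderSpec(kind="fpn", fpn_segmentation_channels=24), espec)
        assert dec.out_channels == 24

    def test_selfonn_q1_equals_plain_unet_preactivation(self, rng):
        """With q=1 and activations/norm removed, the Self-ONN decoder is an
        ordinary convolutional decoder with identical weights."""
        espec = EncoderSpec(family="tiny", in_channels=1)
        enc = build_encoder(espec, rng=np.random.default_rng(0))
        kwargs = dict(decoder_channels=(12, 10, 8, 8, 8), activation="none")
        onn = UnetDecoder(espec.stage_channels, unit_kind="selfonn", q=1,
                          rng=np.random.default_rng(1), **kwargs)
        plain = UnetDecoder(espec.stage_channels, unit_kind="conv", use_batchnorm=False,
                            rng=np.random.default_rng(2), **kwargs)
        onn_params = dict(onn.named_parameters())
        for name, p in plain.named_parameters():
            src = onn_params[name]
            p.data = src.data[0] if src.data.ndim == 5 else src.data.copy()
        feats = enc.eval()(Tensor(rng.standard_normal((1, 1, 64, 64))))
        diff = np.abs(onn(feats).data - plain(feats).data).max()
        assert diff < 1e-5

    def test_doubling_q_adds_exactly_per_power_kernels(self):
        stage = EncoderSpec(family="tiny", in_channels=1).stage_channels
        d = (16, 12, 8, 8, 8)
        n3 = selfonn_unet_decoder_parameter_count(stage, d, 3)
        n6 = selfonn_unet_decoder_parameter_count(stage, d, 6)
        weights_per_power = (selfonn_unet_decoder_parameter_count(stage, d, 2)
                             - selfonn_unet_decoder_parameter_count(stage, d, 1))
        assert n6 - n3 == 3 * weights_per_power

    def test_closed_form_matches_instantiated_decoder(self):
        espec = EncoderSpec(family="tiny", in_channels=1)
        dspec = DecoderSpec(kind="selfonn_unet", decoder_channels=(16, 12, 8, 8, 8), q=3)
        model = build_model(SegmentationModelSpec(encoder=espec, decoder=dspec))
        expected = (count_parameters(model.encoder)
                    + selfonn_unet_decoder_parameter_count(
                        espec.stage_channels, dspec.decoder_channels, dspec.q))
        assert count_parameters(model) == expected


class TestAssembledModels:
    def test_probabilities_sum_to_one(self, tiny_model, rng):
        probs = tiny_model.predict_proba(rng.uniform(0, 255, (64, 64)))
        assert probs.shape == (2, 64, 64)
        assert np.abs(probs.sum(axis=0) - 1.0).max() < 1e-6

    def test_construction_and_forward_deterministic(self, rng):
        from onnseg.experiments import tiny_selfonn_spec
        img = rng.uniform(0, 255, (64, 64))
        a = build_model(tiny_selfonn_spec(seed=9)).predict_proba(img)
        b = build_model(tiny_selfonn_spec(seed=9)).predict_proba(img)
        assert np.array_equal(a, b)

    def test_single_selfonn_layer_parameter_count(self):
        from onnseg import nn
        layer = nn.SelfONN2d(1, 2, 3, q=3)
        assert sum(p.data.size for p in layer.parameters()) == 56

    def test_five_training_steps_stay_finite(self, rng):
        from onnseg import nn as onnn
        from onnseg.experiments import tiny_selfonn_spec
        from onnseg.metrics_losses import dice_loss_tensor
        from onnseg.train import _foreground
        model = build_model(tiny_selfonn_spec(seed=2))
        opt = onnn.Adam(model.parameters(), lr=1e-3)
        x = Tensor(rng.uniform(-1, 1, (2, 1, 64, 64)))
        y = (rng.uniform(0, 1, (2, 64, 64)) > 0.7).astype(float)
        for _ in range(5):
            loss = dice_loss_tensor(_foreground(model(x)), y, per_sample=True)
            opt.zero_grad()
            loss.backward()
            opt.step()
            assert np.isfinite(loss.item())
        assert all(np.all(np.isfinite(p.data)) for p in model.parameters())


class TestSerialization:
    def test_yaml_round_trip(self):
        from onnseg.experiments import tiny_selfonn_spec
        spec = tiny_selfonn_spec(seed=3)
        assert spec_from_yaml(spec_to_yaml(spec)) == spec

    def test_checkpoint_round_trip(self, tmp_path, tiny_model, rng):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_model)
        restored = load_checkpoint(path)
        img = rng.uniform(0, 255, (64, 64))
        assert np.array_equal(tiny_model.predict_proba(img), restored.predict_proba(img))
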