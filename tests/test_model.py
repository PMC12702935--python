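"""Network assembly: toggles, shapes, gradients, determinism, checkpoints."""

import numpy as np
import pytest

from iap_transunet.blocks_sepconv import count_parameters
from iap_transunet.model import ModelConfig, build_model
from iap_transunet.nn import Tensor
from iap_transunet.objectives_metrics import total_loss_logits
from iap_transunet.pipeline import (ABLATION_VARIANTS, ablation_grid,
                                    desk_model_config, load_checkpoint,
                                    save_checkpoint)


def _desk(**kw):
    return desk_model_config(num_classes=4, **kw)


class TestModelConfig:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(num_classes=1), "num_classes"),
        (dict(num_classes=4, input_size=100), "input_size"),
        (dict(num_classes=4, patch_size=8), "patch_size"),
        (dict(num_classes=4, preset="huge"), "preset"),
        (dict(num_classes=4, width_multiplier=0.0), "width_multiplier"),
        (dict(num_classes=4, norm="instance"), "norm"),
        (dict(num_classes=4, decoder_channels=(64, 16)), "decoder_channels"),
    ])
    def test_invalid_config_names_the_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            ModelConfig(**kwargs)

    def test_round_trip_through_dict(self):
        cfg = _desk(use_dsc=False, aspp_rates=(3, 6, 9, 12))
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_presets_resolve_head_compatible_dims(self):
        paper = ModelConfig(num_classes=4, preset="paper-text")
        wide = ModelConfig(num_classes=4, preset="wide")
        assert paper.embed_dim == 512 and paper.embed_dim % paper.n_heads == 0
        assert wide.embed_dim == 768 and wide.embed_dim % wide.n_heads == 0
        quarter = _desk()
        assert quarter.embed_dim % quarter.n_heads == 0

    def test_token_count_follows_input_size(self):
        assert ModelConfig(num_classes=4, input_size=256).n_tokens == 256
        assert _desk().n_tokens == 16


class TestForwardContracts:
    def test_full_resolution_logits_shape(self, rng):
        model = build_model(_desk(), seed=0)
        x = Tensor(rng.standard_normal((2, 1, 64, 64)).astype(np.float32))
        assert model(x).shape == (2, 4, 64, 64)

    def test_nine_class_contract_at_larger_input(self, rng):
        # Synapse-like: 8 organs + background
        cfg = ModelConfig(num_classes=9, in_channels=3, input_size=128,
                          width_multiplier=0.25, dropout=0.0)
        model = build_model(cfg, seed=0)
        x = Tensor(rng.standard_normal((1, 3, 128, 128)).astype(np.float32))
        assert model(x).shape == (1, 9, 128, 128)

    def test_per_pixel_softmax_sums_to_one(self, rng):
        model = build_model(_desk(), seed=0)
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        probs = model(x).softmax(axis=1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_hybrid_encode_tokens_and_skip_pyramid(self, rng):
        cfg = _desk()
        model = build_model(cfg, seed=0)
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        tokens, skips = model.hybrid_encode(x)
        assert tokens.shape == (1, 16, cfg.embed_dim)
        assert [s.shape[2] for s in skips] == [8, 16, 32]   # 1/8, 1/4, 1/2

    def test_per_block_eca_placement_adds_more_gates(self, rng):
        per_stage = build_model(_desk(eca_placement="stage"), seed=0)
        per_block = build_model(_desk(eca_placement="block"), seed=0)
        stage_gates = sum(1 for n, m in per_stage.named_modules()
                          if type(m).__name__ == "EcaAttention")
        block_gates = sum(1 for n, m in per_block.named_modules()
                          if type(m).__name__ == "EcaAttention")
        # 16 residual blocks vs 4 stages (stem and decoder gates unchanged)
        assert block_gates - stage_gates == 16 - 4
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        assert per_block(x).shape == (1, 4, 64, 64)

    def test_group_norm_variant_builds_and_runs(self, rng):
        model = build_model(_desk(norm="group"), seed=0)
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        out = model(x)
        assert out.shape == (1, 4, 64, 64)
        assert np.all(np.isfinite(out.data))

    def test_learned_positional_encoding_variant(self, rng):
        model = build_model(_desk(pos_encoding="learned"), seed=0)
        assert any(name == "pos_table" for name, _ in model.named_parameters())
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        assert model(x).shape == (1, 4, 64, 64)

    def test_wrong_input_size_rejected(self, rng):
        model = build_model(_desk(), seed=0)
        x = Tensor(rng.standard_normal((1, 1, 32, 32)).astype(np.float32))
        with pytest.raises(ValueError, match="input"):
            model(x)

    def test_non_square_token_count_rejected(self, rng):
        model = build_model(_desk(), seed=0)
        bad = Tensor(rng.standard_normal((1, 15, model.cfg.embed_dim))
                     .astype(np.float32))
        with pytest.raises(ValueError, match="square"):
            model.bottleneck(bad)

    def test_bottleneck_passthrough_without_cbam_aspp(self, rng):
        model = build_model(_desk(use_cbam_aspp=False), seed=0)
        tokens = Tensor(rng.standard_normal((1, 16, model.cfg.embed_dim))
                        .astype(np.float32))
        fmap = model.bottleneck(tokens)
        assert fmap.shape == (1, model.cfg.embed_dim, 4, 4)
        expected = tokens.data.transpose(0, 2, 1).reshape(fmap.shape)
        np.testing.assert_allclose(fmap.data, expected)


class TestToggleGrid:
    def test_all_eight_variants_build_and_emit_logits(self, rng):
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        for name, cfg in ablation_grid(_desk()):
            model = build_model(cfg, seed=0)
            assert model(x).shape == (1, 4, 64, 64), name

    def test_check_mark_pattern_matches_the_variant_table(self):
        assert ABLATION_VARIANTS["TransUNet"] == (False, False, False)
        assert ABLATION_VARIANTS["Model1"] == (True, False, False)
        assert ABLATION_VARIANTS["Model6"] == (False, True, True)
        assert ABLATION_VARIANTS["IAP-TransUNet"] == (True, True, True)

    def test_parameter_count_ordering(self):
        base = _desk(use_eca=False, use_cbam_aspp=False, use_dsc=False)
        p0 = count_parameters(build_model(base, seed=0))
        for toggle, expect_more in [("use_eca", True),
                                    ("use_cbam_aspp", True),
                                    ("use_dsc", False)]:
            cfg = ModelConfig.from_dict({**base.to_dict(), toggle: True})
            p = count_parameters(build_model(cfg, seed=0))
            assert (p > p0) == expect_more, toggle

    def test_cbam_aspp_param_difference_is_exactly_the_block(self):
        off = build_model(_desk(use_cbam_aspp=False), seed=0)
        on = build_model(_desk(use_cbam_aspp=True), seed=0)
        diff = count_parameters(on) - count_parameters(off)
        assert diff == count_parameters(on.neck)


class TestTrainingMechanics:
    def test_gradient_reaches_every_parameter(self, rng, tiny_phantom_batch):
        _, images, labels = tiny_phantom_batch
        model = build_model(_desk(), seed=0)
        model.train()
        loss = total_loss_logits(model(Tensor(images)), labels)
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []
        bad = [name for name, p in model.named_parameters()
               if p.grad is not None and not np.all(np.isfinite(p.grad))]
        assert bad == []

    def test_forward_is_deterministic_given_seed(self, rng):
        x = rng.standard_normal((1, 1, 64, 64)).astype(np.float32)
        a = build_model(_desk(), seed=11)(Tensor(x)).data
        b = build_model(_desk(), seed=11)(Tensor(x)).data
        np.testing.assert_array_equal(a, b)
        c = build_model(_desk(), seed=12)(Tensor(x)).data
        assert not np.array_equal(a, c)

    def test_checkpoint_round_trip_is_bit_exact(self, rng, tmp_path):
        model = build_model(_desk(), seed=5)
        model.eval()
        x = Tensor(rng.standard_normal((1, 1, 64, 64)).astype(np.float32))
        before = model(x).data
        path = save_checkpoint(tmp_path / "model", model)
        restored = load_checkpoint(path)
        restored.eval()
        np.testing.assert_array_equal(restored(x).data, before)
        assert restored.cfg == model.cfg
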