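"""Architecture contracts: shapes, branch structure, ablations, gradients."""

import numpy as np
import pytest

from conftest import micro_config
from tunet import losses
from tunet.autodiff import Tensor
from tunet.network import (ConfigError, ModelConfig, PatchTransformerNet,
                           TUNet, build_model, tiny_config)


def _rand_batch(rng, n, size):
    return Tensor(rng.uniform(size=(n, 1, size, size)).astype(np.float32))


class TestConfigValidation:
    def test_indivisible_heads_rejected_before_weights(self):
        with pytest.raises(ConfigError, match="num_heads"):
            build_model(micro_config(embed_dim=30, num_heads=4))

    def test_wrong_rate_count(self):
        with pytest.raises(ConfigError, match="atrous_rates"):
            micro_config(atrous_rates=(1, 3, 5)).validate()

    def test_pool_field_exceeding_bottleneck(self):
        with pytest.raises(ConfigError, match="pool_fields"):
            micro_config(pool_fields=(2, 4, 8, 16), image_size=64).validate()

    def test_unknown_ablation(self):
        with pytest.raises(ConfigError, match="ablation"):
            micro_config(ablation="half_attention").validate()


class TestBuildDeterminism:
    def test_same_seed_same_weights(self):
        cfg = micro_config()
        m1, m2 = build_model(cfg, seed=3), build_model(cfg, seed=3)
        for (k1, p1), (k2, p2) in zip(m1.named_parameters(),
                                      m2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_different_seed_different_weights(self):
        cfg = micro_config()
        m1, m2 = build_model(cfg, seed=0), build_model(cfg, seed=1)
        assert any(not np.array_equal(p1.data, p2.data)
                   for p1, p2 in zip(m1.parameters(), m2.parameters()))


class TestEncoder:
    def test_stride_and_channel_contract(self, rng):
        cfg = micro_config()
        m = build_model(cfg, seed=0)
        skips, bottleneck = m.encode(_rand_batch(rng, 1, 64))
        sizes = [s.shape for s in skips]
        assert sizes == [(1, 4, 64, 64), (1, 8, 32, 32), (1, 12, 16, 16),
                         (1, 16, 8, 8)]
        assert bottleneck.shape == (1, 20, 4, 4)

    def test_bottleneck_spatial_arithmetic(self, rng):
        m = build_model(micro_config(image_size=160), seed=0)
        _, bot = m.encode(_rand_batch(rng, 1, 160))
        assert bot.shape[2:] == (10, 10)  # 160 / 16


class TestPatchEmbedAndTransformer:
    def test_token_count_formula(self, rng):
        """N = H*W/P^2: a 64x64 input with P=16 gives 16 tokens."""
        m = build_model(micro_config(), seed=0)
        _, bot = m.encode(_rand_batch(rng, 1, 64))
        z = m.transformer.embed(bot)
        assert z.shape == (1, 64 * 64 // 16 ** 2, 16)

    def test_single_patch(self, rng):
        m = build_model(micro_config(image_size=16, pool_fields=(1, 1, 1, 1)),
                        seed=0)
        _, bot = m.encode(_rand_batch(rng, 1, 16))
        assert m.transformer.embed(bot).shape[1] == 1

    def test_zero_input_tokens_are_pos_plus_bias(self):
        m = build_model(micro_config(), seed=0)
        bot = Tensor(np.zeros((1, 20, 4, 4), dtype=np.float32))
        z = m.transformer.embed(bot).data
        emb = m.transformer.embed
        expected = (emb.pos.data.reshape(1, 16, 16).transpose(0, 2, 1)
                    + emb.proj.bias.data)
        np.testing.assert_allclose(z, expected, atol=1e-6)

    def test_l0_stack_is_identity_up_to_final_norm(self, rng):
        m = build_model(micro_config(num_layers=0), seed=0)
        assert len(m.transformer.blocks) == 0
        x = Tensor(rng.normal(size=(1, 5, 16)).astype(np.float32))
        z = x
        for blk in m.transformer.blocks:
            z = blk(z)
        np.testing.assert_array_equal(z.data, x.data)

    def test_blocks_preserve_shape(self, rng):
        m = build_model(micro_config(num_layers=2), seed=0)
        z = Tensor(rng.normal(size=(2, 16, 16)).astype(np.float32))
        for blk in m.transformer.blocks:
            z2 = blk(z)
            assert z2.shape == z.shape
            z = z2

    def test_content_equivariance_under_joint_permutation(self, rng):
        """Permuting tokens together with their position information and
        un-permuting afterwards leaves the stack output unchanged."""
        m = build_model(micro_config(num_layers=2), seed=0)
        z = Tensor(rng.normal(size=(1, 16, 16)).astype(np.float64))
        perm = rng.permutation(16)
        inv = np.argsort(perm)

        def run(tokens):
            out = tokens
            for blk in m.transformer.blocks:
                out = blk(out)
            return m.transformer.norm(out).data

        out_direct = run(z)
        out_perm = run(Tensor(z.data[:, perm]))[:, inv]
        np.testing.assert_allclose(out_perm, out_direct, atol=1e-5)


class TestConvBranch:
    def test_atrous_preserves_spatial_size(self, rng):
        m = build_model(micro_config(), seed=0)
        x = Tensor(rng.normal(size=(1, 20, 8, 8)).astype(np.float32))
        assert m.atrous(x).shape == (1, 20, 8, 8)

    def test_atrous_rates_recorded(self):
        m = build_model(micro_config(), seed=0)
        assert m.atrous.rates == (1, 3, 5, 7)

    def test_cascade_receptive_field_grows(self, rng):
        """A centred impulse spreads over a strictly wider support after each
        cascaded dilated stage."""
        m = build_model(micro_config(), seed=0)
        m.eval()
        zero = np.zeros((1, 20, 33, 33), dtype=np.float32)
        imp = zero.copy()
        imp[0, :, 16, 16] = 1.0
        supports = []
        h_imp, h_zero = Tensor(imp), Tensor(zero)
        for br in m.atrous.branches:
            h_imp = br(h_imp).relu()
            h_zero = br(h_zero).relu()
            resp = np.abs(h_imp.data[0] - h_zero.data[0]).max(axis=0) > 1e-12
            rows = np.where(resp.any(axis=1))[0]
            supports.append(rows.max() - rows.min() + 1)
        assert all(b > a for a, b in zip(supports, supports[1:]))

    def test_pyramid_output_channels_and_fields(self, rng):
        m = build_model(micro_config(), seed=0)
        assert m.pyramid.fields == (1, 2, 2, 4)
        x = Tensor(rng.normal(size=(1, 20, 4, 4)).astype(np.float32))
        assert m.pyramid(x).shape == (1, 20, 4, 4)

    def test_pyramid_constant_propagation(self):
        """Averaging a constant map reproduces the constant in each branch."""
        m = build_model(micro_config(), seed=0)
        x = Tensor(np.full((1, 20, 4, 4), 0.7, dtype=np.float32))
        for f in m.pyramid.fields:
            pooled = x.avg_pool2d(f).upsample_bilinear((4, 4)).data
            np.testing.assert_allclose(pooled, 0.7, atol=1e-6)

    def test_pyramid_field_larger_than_map_raises(self, rng):
        m = build_model(micro_config(), seed=0)
        x = Tensor(rng.normal(size=(1, 20, 2, 2)).astype(np.float32))
        with pytest.raises(ConfigError, match="pool_fields"):
            m.pyramid(x)

    def test_default_fields_match_reference(self):
        assert ModelConfig().pool_fields == (2, 4, 8, 16)


class TestFusionAndAblation:
    @pytest.mark.parametrize("abl", ["no_transformer", "transformer_only_bottleneck"])
    def test_single_branch_fusion_is_identity_on_that_branch(self, rng, abl):
        m = build_model(micro_config(ablation=abl), seed=0)
        bot = Tensor(rng.normal(size=(1, 20, 4, 4)).astype(np.float32))
        m.eval()
        out = m.attention(bot)
        if abl == "no_transformer":
            ref = m.conv_branch(bot)
        else:
            ref = m.token_proj(m.transformer(bot))
        np.testing.assert_array_equal(out.data, ref.data)

    def test_no_attention_is_bottleneck_passthrough(self, rng):
        m = build_model(micro_config(ablation="no_attention"), seed=0)
        bot = Tensor(rng.normal(size=(1, 20, 4, 4)).astype(np.float32))
        assert m.attention(bot) is bot
        assert m.transformer is None and m.atrous is None

    def test_full_fusion_output_matches_bottleneck_shape(self, rng):
        m = build_model(micro_config(), seed=0)
        m.eval()
        bot = Tensor(rng.normal(size=(1, 20, 4, 4)).astype(np.float32))
        assert m.attention(bot).shape == bot.shape

    def test_parameter_count_ordering(self):
        counts = {abl: build_model(micro_config(ablation=abl), seed=0)
                  .num_parameters()
                  for abl in ("full", "no_attention", "no_transformer",
                              "transformer_only_bottleneck",
                              "patch_input_transformer")}
        assert counts["no_attention"] < counts["full"]
        assert counts["no_transformer"] < counts["full"]
        assert counts["patch_input_transformer"] < counts[
            "transformer_only_bottleneck"]

    def test_full_minus_aunet_equals_transformer_branch(self):
        full = build_model(micro_config(), seed=0)
        aunet = build_model(micro_config(ablation="no_transformer"), seed=0)
        assert (full.num_parameters() - aunet.num_parameters()
                == full.transformer_branch_parameters())


class TestDecoderAndForward:
    def test_logits_at_input_resolution(self, rng):
        m = build_model(micro_config(), seed=0)
        m.eval()
        out = m(_rand_batch(rng, 2, 64))
        assert out.shape == (2, 1, 64, 64)

    def test_missing_skip_raises(self, rng):
        m = build_model(micro_config(), seed=0)
        skips, bot = m.encode(_rand_batch(rng, 1, 64))
        with pytest.raises(ValueError, match="skip"):
            m.decoder(m.attention(bot), skips[:-1])

    def test_skips_are_live_paths(self, rng):
        """Zeroing a skip connection changes the output."""
        m = build_model(micro_config(), seed=0)
        m.eval()
        x = _rand_batch(rng, 1, 64)
        skips, bot = m.encode(x)
        base = m.decoder(m.attention(bot), skips).data
        for i in range(len(skips)):
            cut = list(skips)
            cut[i] = Tensor(np.zeros_like(cut[i].data))
            alt = m.decoder(m.attention(bot), cut).data
            assert np.abs(alt - base).max() > 0

    @pytest.mark.parametrize("size", [64, 96, 160])
    def test_shape_contract_across_sizes(self, rng, size):
        m = build_model(micro_config(), seed=0)
        m.eval()
        out = m(_rand_batch(rng, 1, size))
        assert out.shape == (1, 1, size, size)
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_eval_forward_deterministic(self, rng):
        m = build_model(micro_config(), seed=0)
        m.eval()
        x = _rand_batch(rng, 1, 64)
        np.testing.assert_array_equal(m(x).data, m(x).data)

    def test_batch_equals_singles_in_eval(self, rng):
        m = build_model(micro_config(), seed=0)
        m.eval()
        x = rng.uniform(size=(2, 1, 64, 64)).astype(np.float32)
        joint = m(Tensor(x)).data
        singles = np.concatenate([m(Tensor(x[i:i + 1])).data for i in range(2)])
        np.testing.assert_allclose(joint, singles, atol=1e-5)

    def test_gradient_completeness(self, rng):
        """Every trainable parameter gets a finite, not-identically-zero
        gradient from one joint-loss backward pass."""
        m = build_model(micro_config(), seed=0)
        x = _rand_batch(rng, 2, 64)
        y = (rng.uniform(size=(2, 1, 64, 64)) > 0.6).astype(np.uint8)
        res = losses.joint_loss(m(x), y)
        res.total.backward()
        for name, p in m.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name
            assert np.any(p.grad != 0), name

    def test_patch_input_transformer_end_to_end(self, rng):
        m = build_model(micro_config(ablation="patch_input_transformer"), seed=0)
        assert isinstance(m, PatchTransformerNet)
        out = m(_rand_batch(rng, 1, 64))
        assert out.shape == (1, 1, 64, 64)


class TestDefaultArchitecture:
    def test_tiny_config_valid(self):
        tiny_config().validate()

    def test_default_config_structure(self):
        cfg = ModelConfig()
        assert cfg.base_channels == (64, 128, 256, 512, 1024)
        assert cfg.num_layers == 12
        assert cfg.atrous_rates == (1, 3, 5, 7)
        cfg.validate()
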