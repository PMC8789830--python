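"""Forward contracts of the SR/QE generator and the discriminator."""

import numpy as np
import pytest

from octarec._autograd import Tensor
from octarec.nets import (DeepLayer, Discriminator, Generator, NetConfig,
                          load_generator, pixel_shuffle, save_generator)


def small_cfg(**kw):
    defaults = dict(connection="dense", n_blocks=2, base_channels=6,
                    upsample_ratio=2)
    defaults.update(kw)
    return NetConfig(**defaults)


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"connection": "skip"}, {"n_blocks": 0}, {"upsample_ratio": 3},
        {"outer_kernel": 8}, {"inner_kernel": 4},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)


class TestPixelShuffle:
    def test_identity_at_scale_one(self, rng):
        x = rng.normal(size=(4, 3, 3))
        assert np.array_equal(pixel_shuffle(x, 1), x)

    def test_two_by_two_plane_from_four_channels(self):
        x = np.arange(4, dtype=float).reshape(4, 1, 1)
        assert np.array_equal(pixel_shuffle(x, 2), [[[0.0, 1.0], [2.0, 3.0]]])

    @pytest.mark.parametrize("s", [2, 4])
    def test_matches_index_formula_oracle(self, s, rng):
        """Brute-force enumeration of the periodic rearrangement."""
        c, h, w = 3, 4, 5
        x = rng.normal(size=(c * s * s, h, w))
        out = pixel_shuffle(x, s)
        assert out.shape == (c, s * h, s * w)
        for ci in range(c):
            for hi in range(h):
                for wi in range(w):
                    for a in range(s):
                        for b in range(s):
                            assert out[ci, s * hi + a, s * wi + b] == \
                                x[ci * s * s + a * s + b, hi, wi]

    def test_inverse_round_trip(self, rng):
        x = rng.normal(size=(8, 3, 3))
        out = pixel_shuffle(x, 2)
        back = (out.reshape(2, 3, 2, 3, 2).transpose(0, 2, 4, 1, 3)
                .reshape(8, 3, 3))
        assert np.array_equal(back, x)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError):
            pixel_shuffle(np.zeros((6, 2, 2)), 2)


class TestDeepLayer:
    def test_residual_zero_weights_is_identity(self, rng):
        cfg = small_cfg(connection="residual")
        layer = DeepLayer(cfg, np.random.default_rng(0))
        for conv in layer.convs:
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 6, 8, 8)))
        assert np.array_equal(layer(x).data, x.data)

    def test_spatial_shape_preserved(self, rng):
        x = Tensor(rng.normal(size=(2, 6, 9, 11)))
        for conn in ("dense", "residual"):
            layer = DeepLayer(small_cfg(connection=conn),
                              np.random.default_rng(0))
            assert layer(x).shape == x.shape

    def test_dense_fusion_channel_arithmetic(self):
        """Fusion consumes the layer input plus all n block outputs."""
        cfg = small_cfg(connection="dense", n_blocks=5, base_channels=4)
        layer = DeepLayer(cfg, np.random.default_rng(0))
        assert layer.fusion.weight.shape == (4, 4 * (5 + 1), 1, 1)
        # block k sees input channels 4*(k+1)
        assert [c.weight.shape[1] for c in layer.convs] == \
            [4 * (b + 1) for b in range(5)]


class TestGeneratorForward:
    @pytest.mark.parametrize("r", [2, 4, 8])
    def test_output_shape_law(self, r, rng):
        G = Generator(small_cfg(upsample_ratio=r), seed=0)
        out = G.reconstruct(rng.uniform(0, 1, (8, 8)))
        assert out.shape == (8 * r, 8 * r)

    def test_sr_shape_and_bounds(self, rng):
        G = Generator(small_cfg(upsample_ratio=4), seed=1)
        out = G.sr_forward(rng.uniform(0, 1, (32, 32)))
        assert out.shape == (128, 128)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_qe_preserves_shape(self, rng):
        G = Generator(small_cfg(), seed=0)
        for shape in [(16, 16), (24, 20)]:
            out = G.qe_forward(rng.uniform(0, 1, shape))
            assert out.shape == shape
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic_given_seed(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        a = Generator(small_cfg(), seed=3).reconstruct(img)
        b = Generator(small_cfg(), seed=3).reconstruct(img)
        assert np.array_equal(a, b)

    def test_equals_explicit_module_composition(self, rng):
        G = Generator(small_cfg(), seed=0)
        img = rng.uniform(0, 1, (8, 8))
        assert np.array_equal(G.reconstruct(img),
                              G.qe_forward(G.sr_forward(img)))

    def test_batch_order_preserved(self, rng):
        G = Generator(small_cfg(), seed=0)
        batch = rng.uniform(0, 1, (3, 8, 8))
        outs = G.reconstruct(batch)
        assert outs.shape == (3, 16, 16)
        for i in range(3):
            assert np.allclose(outs[i], G.reconstruct(batch[i]), atol=1e-12)

    def test_deep_layer_weights_change_output(self, rng):
        G = Generator(small_cfg(connection="residual"), seed=0)
        img = rng.uniform(0, 1, (8, 8))
        base = G.qe_forward(img)
        G.qe.deep.convs[0].weight.data += 0.5
        assert not np.allclose(G.qe_forward(img), base)

    def test_forward_nan_free_for_he_initialized_weights(self, rng):
        for seed in range(3):
            G = Generator(small_cfg(), seed=seed)
            out = G.reconstruct(rng.uniform(0, 1, (12, 12)))
            assert np.all(np.isfinite(out))


class TestDiscriminator:
    def test_probability_strictly_inside_unit_interval(self, rng):
        D = Discriminator(base_channels=8, seed=0)
        p = D.predict(rng.uniform(0, 1, (2, 32, 32)))
        assert np.all((p > 0) & (p < 1))

    def test_deterministic_in_eval_mode(self, rng):
        D = Discriminator(base_channels=8, seed=0)
        img = rng.uniform(0, 1, (32, 32))
        assert np.array_equal(D.predict(img), D.predict(img))

    def test_constant_images_give_finite_distinct_outputs(self):
        D = Discriminator(base_channels=8, seed=2)
        p = D.predict(np.stack([np.zeros((32, 32)), np.ones((32, 32))]))
        assert np.all(np.isfinite(p))
        assert p[0] != p[1]


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        G = Generator(small_cfg(), seed=0)
        img = rng.uniform(0, 1, (8, 8))
        before = G.reconstruct(img)
        path = tmp_path / "gen.npz"
        save_generator(G, path)
        G2 = load_generator(path)
        assert G2.cfg == G.cfg
        assert np.array_equal(G2.reconstruct(img), before)
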