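"""Latent layout bookkeeping, forward passes and checkpoints."""

import numpy as np
import pytest

from phenocae import model
from phenocae.model import (
    Checkpoint,
    LatentLayout,
    NetworkSpec,
    ShapeError,
    cae_forward,
    compose,
    decode,
    encode,
    fuse,
    vanilla_forward,
)


def make_params(spec, layout=None, d=None, seed=0):
    shapes = model.param_shapes(spec, layout, d=d)
    return shapes, model.init_params(shapes, seed)


class TestLatentLayout:
    @pytest.mark.parametrize(
        "zg, ze, zp, d, D",
        [(12, 4, 4, 20, 36), (6, 2, 2, 10, 18), (24, 8, 8, 40, 72), (48, 16, 16, 80, 144)],
    )
    def test_standard_layout_dimensions(self, zg, ze, zp, d, D):
        lay = LatentLayout(zg, ze, zp, E=2, N=2)
        assert lay.d == d
        assert lay.D == D  # zg + E*ze + P*zp

    def test_slot_map_is_total_and_non_overlapping(self, tiny_layout):
        lay = tiny_layout
        covered = list(range(*lay.zg_slice().indices(lay.D)))
        for e in range(lay.E):
            covered += list(range(*lay.ze_slice(e).indices(lay.D)))
        for p in range(lay.P):
            covered += list(range(*lay.zp_slice(p).indices(lay.D)))
        assert sorted(covered) == list(range(lay.D))
        assert len(set(covered)) == lay.D

    def test_environment_assignment_follows_canonical_order(self):
        lay = LatentLayout(3, 2, 2, E=2, N=2)
        assert [lay.environment_of(p) for p in range(4)] == [0, 0, 1, 1]

    def test_identity_case(self):
        lay = LatentLayout(3, 2, 2, E=1, N=1)
        assert lay.D == lay.d

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            LatentLayout(0, 1, 1)


class TestComposition:
    def test_compose_gathers_correct_slots(self, tiny_layout):
        lay = tiny_layout
        fused = np.arange(lay.D, dtype=float)
        # plant 0 (first replicate of env 1): [Zg, Ze(1), Zp(1)]
        c0 = compose(fused, 0, lay)
        np.testing.assert_array_equal(c0[: lay.zg], fused[lay.zg_slice()])
        np.testing.assert_array_equal(c0[lay.zg : lay.zg + lay.ze], fused[lay.ze_slice(0)])
        np.testing.assert_array_equal(c0[lay.zg + lay.ze :], fused[lay.zp_slice(0)])
        # plant 2 (first replicate of env 2): [Zg, Ze(2), Zp(3)]
        c2 = compose(fused, 2, lay)
        np.testing.assert_array_equal(c2[lay.zg : lay.zg + lay.ze], fused[lay.ze_slice(1)])
        np.testing.assert_array_equal(c2[lay.zg + lay.ze :], fused[lay.zp_slice(2)])

    def test_zero_fused_gives_zero_composed(self, tiny_layout):
        assert not compose(np.zeros(tiny_layout.D), 1, tiny_layout).any()

    def test_out_of_range_plant(self, tiny_layout):
        with pytest.raises(IndexError):
            compose(np.zeros(tiny_layout.D), tiny_layout.P, tiny_layout)

    def test_split_then_concat_is_identity(self, tiny_layout):
        lay = tiny_layout
        fused = np.random.default_rng(0).normal(size=lay.D)
        parts = [fused[lay.zg_slice()]]
        parts += [fused[lay.ze_slice(e)] for e in range(lay.E)]
        parts += [fused[lay.zp_slice(p)] for p in range(lay.P)]
        np.testing.assert_array_equal(np.concatenate(parts), fused)


class TestForwardPasses:
    def test_encode_output_width_and_determinism(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        enc, _, _ = model.unpack_params(theta, shapes)
        x = np.random.default_rng(0).random((5, 30))
        z1, z2 = encode(x, tiny_spec, enc), encode(x, tiny_spec, enc)
        assert z1.shape == (5, tiny_layout.d)
        np.testing.assert_array_equal(z1, z2)

    def test_encode_zero_weights_give_zero(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        enc, _, _ = model.unpack_params(np.zeros_like(theta), shapes)
        z = encode(np.random.default_rng(1).random((3, 30)), tiny_spec, enc)
        np.testing.assert_array_equal(z, np.zeros((3, tiny_layout.d)))

    def test_encode_width_mismatch(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        enc, _, _ = model.unpack_params(theta, shapes)
        with pytest.raises(ShapeError):
            encode(np.zeros((2, 31)), tiny_spec, enc)

    def test_decode_zero_params_give_half(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        _, _, dec = model.unpack_params(np.zeros_like(theta), shapes)
        out = decode(np.zeros((4, tiny_layout.d)), tiny_spec, dec)
        np.testing.assert_allclose(out, 0.5)  # sigmoid(0)

    def test_decode_range_and_shape(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        _, _, dec = model.unpack_params(theta, shapes)
        out = decode(np.random.default_rng(2).normal(size=(6, tiny_layout.d)), tiny_spec, dec)
        assert out.shape == (6, 30)
        assert np.all((out > 0) & (out < 1))

    def test_fuse_is_linear_in_inputs(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        _, fusion, _ = model.unpack_params(theta, shapes)
        w, b = fusion
        rng = np.random.default_rng(3)
        X = rng.normal(size=(tiny_layout.P, tiny_layout.d))
        Y = rng.normal(size=(tiny_layout.P, tiny_layout.d))
        lhs = fuse(2.0 * X + 3.0 * Y, tiny_layout, (w, np.zeros_like(b)))
        rhs = 2.0 * fuse(X, tiny_layout, (w, np.zeros_like(b))) + 3.0 * fuse(
            Y, tiny_layout, (w, np.zeros_like(b))
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_fuse_wrong_row_count(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        _, fusion, _ = model.unpack_params(theta, shapes)
        with pytest.raises(ShapeError):
            fuse(np.zeros((3, tiny_layout.d)), tiny_layout, fusion)

    def test_cae_forward_shares_genotype_slice(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout, seed=5)
        group = np.random.default_rng(4).random((tiny_layout.P, 30))
        recon, fused = cae_forward(group, tiny_spec, tiny_layout, theta)
        assert recon.shape == (4, 30)
        assert fused.shape == (tiny_layout.D,)
        composed = [compose(fused, p, tiny_layout) for p in range(4)]
        for c in composed[1:]:
            np.testing.assert_array_equal(c[: tiny_layout.zg], composed[0][: tiny_layout.zg])
        # plants 0,1 share env 1; 2,3 share env 2
        ze = slice(tiny_layout.zg, tiny_layout.zg + tiny_layout.ze)
        np.testing.assert_array_equal(composed[0][ze], composed[1][ze])
        np.testing.assert_array_equal(composed[2][ze], composed[3][ze])

    def test_cae_forward_deterministic(self, tiny_spec, tiny_layout):
        shapes, theta = make_params(tiny_spec, tiny_layout)
        group = np.random.default_rng(5).random((4, 30))
        r1, f1 = cae_forward(group, tiny_spec, tiny_layout, theta)
        r2, f2 = cae_forward(group, tiny_spec, tiny_layout, theta)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(f1, f2)

    def test_vanilla_forward_shapes_and_zero_params(self, tiny_spec):
        shapes, theta = make_params(tiny_spec, d=7)
        x = np.random.default_rng(6).random((9, 30))
        recon, z = vanilla_forward(x, tiny_spec, 7, theta)
        assert recon.shape == x.shape and z.shape == (9, 7)
        recon0, _ = vanilla_forward(np.zeros((2, 30)), tiny_spec, 7, np.zeros_like(theta))
        np.testing.assert_allclose(recon0, 0.5)


class TestNetworkSpec:
    def test_parameter_count_closed_form(self):
        spec = NetworkSpec(input_dim=2151, hidden_dims=(2150, 1024, 512))
        d = 20
        expected = (
            (2151 + 1) * 2150 + (2150 + 1) * 1024 + (1024 + 1) * 512 + (512 + 1) * d
            + (d + 1) * 512 + (512 + 1) * 1024 + (1024 + 1) * 2150 + (2150 + 1) * 2151
        )
        assert spec.n_parameters(d) == expected
        lay = LatentLayout(12, 4, 4)
        assert spec.n_parameters(d, lay) == expected + (4 * 20 + 1) * 36

    @pytest.mark.parametrize("hidden", [(512,), (1024, 512), (2150, 1024, 512), (2150, 1400, 1024, 512)])
    def test_depth_variants_constructible(self, hidden):
        spec = NetworkSpec(input_dim=2151, hidden_dims=hidden)
        assert len(spec.encoder_dims(20)) == len(hidden) + 1
        assert spec.encoder_dims(20)[0][0] == 2151
        assert spec.decoder_dims(20)[-1][1] == 2151


class TestCheckpoint:
    def test_roundtrip_reproduces_inference(self, tiny_spec, tiny_layout, tmp_path):
        shapes, theta = make_params(tiny_spec, tiny_layout, seed=9)
        ckpt = Checkpoint(
            model_type="cae",
            theta=theta,
            spec=tiny_spec,
            layout=tiny_layout,
            d=tiny_layout.d,
            environment_order=["e0", "e1"],
            norm_constants=(0.1, 0.9),
            seed=9,
        )
        ckpt.save(tmp_path / "ck")
        loaded = Checkpoint.load(tmp_path / "ck")
        assert loaded.layout == tiny_layout
        assert loaded.spec == tiny_spec
        assert loaded.norm_constants == (0.1, 0.9)
        group = np.random.default_rng(10).random((4, 30))
        r1, _ = cae_forward(group, tiny_spec, tiny_layout, theta)
        r2, _ = cae_forward(group, loaded.spec, loaded.layout, loaded.theta)
        np.testing.assert_array_equal(r1, r2)
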