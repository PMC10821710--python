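"""Autodiff engine and backbone contracts.

The engine is certified by central-difference gradient checks; the backbones
by their shape contracts, activation ranges, determinism and translation
covariance.
"""

import numpy as np
import pytest

from im2im.core import NetworkSpec, NetworkResolutionError, resolve_network
from im2im.nn import (
    Adam,
    BatchNorm,
    InstanceNorm,
    PatchDiscriminator,
    Tensor,
    UNet,
    concatenate,
    gradcheck,
)


class TestGradients:
    def test_conv2d_stride_and_padding(self, rng):
        x = Tensor(rng.standard_normal((2, 3, 6, 7)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 3, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(rng.standard_normal(4) * 0.1, requires_grad=True)
        assert gradcheck(
            lambda x, w, b: (x.conv(w, b, (1, 1), (1, 1)) ** 2).mean(), [x, w, b]
        )
        assert gradcheck(
            lambda x, w, b: (x.conv(w, b, (2, 2), (0, 0)) ** 2).mean(), [x, w, b]
        )

    def test_conv3d_anisotropic_flat_z_kernel(self, rng):
        x = Tensor(rng.standard_normal((1, 2, 3, 6, 6)), requires_grad=True)
        w = Tensor(rng.standard_normal((2, 2, 1, 3, 3)) * 0.3, requires_grad=True)
        assert gradcheck(
            lambda x, w: (x.conv(w, None, (1, 2, 2), (0, 1, 1)).tanh() ** 2).mean(),
            [x, w],
        )

    def test_upsample_concat_norm_and_elementwise(self, rng):
        u = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
        v = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
        assert gradcheck(lambda u: (u.upsample_nearest((2, 2)) ** 2).mean(), [u])
        assert gradcheck(
            lambda u, v: (concatenate([u, v], 1).leaky_relu() ** 2).mean(), [u, v]
        )
        inorm, bnorm = InstanceNorm(2), BatchNorm(2)
        assert gradcheck(lambda u: ((inorm(u) - 1.0) ** 2).mean(), [u])
        assert gradcheck(lambda u: ((bnorm(u) - 1.0) ** 2).mean(), [u])
        assert gradcheck(
            lambda u: (u.sigmoid().clamp(1e-6, 1 - 1e-6).log().abs()).mean(), [u]
        )

    def test_branching_graph_accumulates(self, rng):
        x = Tensor(rng.standard_normal((3, 3)), requires_grad=True)
        assert gradcheck(lambda x: (x * x.tanh() + x.exp() * 0.1).mean(), [x])


class TestAdam:
    def test_converges_on_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (p**2).sum()
            loss.backward()
            opt.step()
        assert np.all(np.abs(p.data) < 1e-2)


class TestUNet:
    def test_shape_contract_2d(self, rng):
        net = UNet(2, 1, 1, rng, depth=3, base_filters=4)
        out = net(Tensor(rng.standard_normal((2, 1, 32, 32))))
        assert out.shape == (2, 1, 32, 32)

    def test_tanh_output_range(self, rng):
        net = UNet(2, 1, 1, rng, depth=2, base_filters=4, final_activation="tanh")
        out = net(Tensor(rng.standard_normal((1, 1, 16, 16)) * 50))
        assert out.data.min() > -1 and out.data.max() < 1

    def test_depth_one_is_conv_block_without_pooling(self, rng):
        net = UNet(2, 1, 1, rng, depth=1, base_filters=4)
        assert net.total_down_factor == (1, 1)
        out = net(Tensor(rng.standard_normal((1, 1, 17, 19))))
        assert out.shape == (1, 1, 17, 19)

    def test_indivisible_extent_names_axis(self, rng):
        net = UNet(2, 1, 1, rng, depth=3, base_filters=4)
        with pytest.raises(ValueError, match="axis Y"):
            net(Tensor(np.zeros((1, 1, 30, 32))))

    def test_anisotropic_z_passes_shallow_stack(self, rng):
        # all-Z-factor-1 transitions: Z=4 passes a 4-level network
        net = UNet(3, 1, 1, rng, depth=4, base_filters=2,
                   down_factors=[(1, 2, 2)] * 3)
        out = net(Tensor(rng.standard_normal((1, 1, 4, 32, 32))))
        assert out.shape == (1, 1, 4, 32, 32)
        # isotropic factors would demand Z divisible by 8
        iso = UNet(3, 1, 1, rng, depth=4, base_filters=2)
        with pytest.raises(ValueError, match="axis Z"):
            iso(Tensor(np.zeros((1, 1, 4, 32, 32))))

    def test_architecture_determinism(self):
        n1 = UNet(2, 1, 1, np.random.default_rng(5), depth=4, base_filters=16)
        n2 = UNet(2, 1, 1, np.random.default_rng(5), depth=4, base_filters=16)
        assert n1.num_parameters() == n2.num_parameters()
        for (k1, p1), (k2, p2) in zip(
            n1.named_parameters(), n2.named_parameters()
        ):
            assert k1 == k2 and np.array_equal(p1.data, p2.data)

    def test_eval_forward_deterministic(self, rng):
        net = UNet(2, 1, 1, rng, depth=2, base_filters=4).eval()
        x = Tensor(rng.standard_normal((1, 1, 16, 16)))
        assert np.array_equal(net(x).data, net(x).data)

    def test_translation_covariance_in_interior(self, rng):
        # shifting the input by a full down-factor stride shifts the output
        # identically away from boundaries
        net = UNet(2, 1, 1, rng, depth=2, base_filters=4, norm="none").eval()
        x = rng.standard_normal((1, 1, 48, 48)).astype(np.float32)
        shifted = np.roll(x, 2, axis=2)
        out = net(Tensor(x)).data
        out_shifted = net(Tensor(shifted)).data
        interior = (slice(None), slice(None), slice(12, 36), slice(12, 36))
        assert np.allclose(
            np.roll(out, 2, axis=2)[interior], out_shifted[interior], atol=1e-4
        )


class TestPatchDiscriminator:
    def test_logit_grid_shape(self, rng):
        d = PatchDiscriminator(2, 2, rng, n_blocks=3)
        out = d(Tensor(rng.standard_normal((1, 2, 64, 64))))
        assert out.shape == (1, 1, 8, 8)

    def test_finite_for_extreme_inputs(self, rng):
        d = PatchDiscriminator(2, 1, rng)
        out = d(Tensor(np.full((1, 1, 32, 32), 1e3, dtype=np.float32)))
        assert np.all(np.isfinite(out.data))

    def test_unconditional_single_channel(self, rng):
        d = PatchDiscriminator(2, 1, rng)
        out = d(Tensor(rng.standard_normal((2, 1, 32, 32))))
        assert out.shape[0] == 2 and out.shape[1] == 1


class TestResolveNetwork:
    def test_builtin_shape_contract(self):
        spec = NetworkSpec(name="unet_2d", dim=2, in_channels=1, out_channels=1,
                           depth=2, base_filters=4)
        net = resolve_network(spec, np.random.default_rng(0))
        out = net(Tensor(np.zeros((1, 1, 16, 16), dtype=np.float32)))
        assert out.shape == (1, 1, 16, 16)

    def test_dotted_path_factory(self):
        spec = NetworkSpec(
            name="tests.netfixtures.make_tiny_net", dim=2,
            in_channels=1, out_channels=1,
            kwargs={"in_channels": 1, "out_channels": 1},
        )
        net = resolve_network(spec)
        from tests.netfixtures import TinyNet

        assert isinstance(net, TinyNet)

    def test_unresolvable_path(self):
        spec = NetworkSpec(name="nonexistent.module.thing", dim=2)
        with pytest.raises(NetworkResolutionError):
            resolve_network(spec)

    def test_channel_contract_mismatch_reported(self):
        spec = NetworkSpec(
            name="tests.netfixtures.make_tiny_net", dim=2,
            in_channels=1, out_channels=3,
            kwargs={"in_channels": 1, "out_channels": 1},
        )
        with pytest.raises(NetworkResolutionError, match="3 output"):
            resolve_network(spec)
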