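"""Framework step logic: degenerate limits, objectives, parameter isolation."""

import numpy as np
import pytest

from im2im.core import FrameworkConfig, NetworkSpec, TrainerConfig
from im2im.frameworks import (
    FCNFramework,
    Pix2PixFramework,
    CycleGANFramework,
    adv_loss,
    build_framework,
    cyclegan_step,
    fcn_step,
    pix2pix_step,
)
from im2im.nn import Module, Tensor


class IdentityNet(Module):
    def forward(self, x):
        return x * 1.0


class ConstantNet(Module):
    def __init__(self, value):
        super().__init__()
        self.value = value

    def forward(self, x):
        return x * 0.0 + self.value


class ShiftNet(Module):
    def __init__(self, c):
        super().__init__()
        self.c = c

    def forward(self, x):
        return x + self.c


def _batch(rng, n=2, c=1, s=16):
    src = rng.normal(size=(n, c, s, s)).astype(np.float32)
    tgt = rng.normal(size=(n, c, s, s)).astype(np.float32)
    return src, tgt, None


class TestFCNStep:
    def test_identity_net_perfect_prediction(self, rng):
        src = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        cfg = FrameworkConfig(kind="fcn", recon_loss="mae")
        loss = fcn_step((src, src.copy(), None), IdentityNet(), cfg)
        assert loss.item() == pytest.approx(0.0, abs=1e-7)

    def test_constant_field(self):
        src = np.zeros((1, 1, 4, 4), dtype=np.float32)
        tgt = np.ones((1, 1, 4, 4), dtype=np.float32)
        cfg = FrameworkConfig(kind="fcn", recon_loss="mae")
        loss = fcn_step((src, tgt, None), ConstantNet(0.0), cfg)
        assert loss.item() == pytest.approx(1.0)

    @pytest.mark.parametrize("kind,expected", [("mae", 0.5), ("mse", 0.25),
                                               ("smooth_mae", 0.125)])
    def test_recon_loss_kinds(self, kind, expected):
        src = np.zeros((1, 1, 2, 2), dtype=np.float32)
        tgt = np.full((1, 1, 2, 2), 0.5, dtype=np.float32)
        cfg = FrameworkConfig(kind="fcn", recon_loss=kind)
        assert fcn_step((src, tgt, None), IdentityNet(), cfg).item() == pytest.approx(
            expected
        )


class TestAdvLoss:
    def test_lsgan_half_confidence_case(self):
        # discriminator output 0.5 on both branches -> 0.5[(0.5-1)^2+(0.5-0)^2]
        logits = Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))  # sigmoid=0.5
        d_loss = 0.5 * (
            adv_loss(logits, True, "lsgan").item()
            + adv_loss(logits, False, "lsgan").item()
        )
        assert d_loss == pytest.approx(0.25)

    def test_vanilla_is_log_sigmoid(self):
        logits = Tensor(np.zeros((1, 1, 2, 2), dtype=np.float32))
        assert adv_loss(logits, True, "vanilla").item() == pytest.approx(
            np.log(2), abs=1e-5
        )


def _nets(rng_seed=0):
    spec = NetworkSpec(name="unet_2d", dim=2, in_channels=1, out_channels=1,
                       depth=2, base_filters=4, final_activation="tanh")
    trainer = TrainerConfig()
    return spec, trainer


class TestPix2Pix:
    def test_zero_adv_weight_equals_scaled_fcn_loss(self, rng):
        spec, trainer = _nets()
        cfg = FrameworkConfig(kind="pix2pix", adv_weight=0.0, recon_weight=1.0,
                              recon_loss="mae")
        fw = Pix2PixFramework(cfg, spec, trainer, np.random.default_rng(0))
        batch = _batch(rng)
        g_loss = pix2pix_step(batch, fw.G, fw.D, cfg, "gen")
        f_loss = fcn_step(batch, fw.G, FrameworkConfig(kind="fcn", recon_loss="mae"))
        assert g_loss.item() == pytest.approx(f_loss.item(), rel=1e-6)

    def test_zero_adv_weight_gradients_equal_fcn(self, rng):
        spec, trainer = _nets()
        cfg = FrameworkConfig(kind="pix2pix", adv_weight=0.0, recon_weight=1.0,
                              recon_loss="mae")
        fw = Pix2PixFramework(cfg, spec, trainer, np.random.default_rng(0))
        batch = _batch(rng)
        for p in fw.G.parameters():
            p.grad = None
        pix2pix_step(batch, fw.G, fw.D, cfg, "gen").backward()
        grads_p2p = [p.grad.copy() for p in fw.G.parameters()]
        for p in fw.G.parameters():
            p.grad = None
        fcn_step(batch, fw.G, FrameworkConfig(kind="fcn", recon_loss="mae")).backward()
        grads_fcn = [p.grad for p in fw.G.parameters()]
        for a, b in zip(grads_p2p, grads_fcn):
            assert np.allclose(a, b, atol=1e-6)

    def test_parameter_isolation_between_phases(self, rng):
        spec, trainer = _nets()
        cfg = FrameworkConfig(kind="pix2pix")
        fw = Pix2PixFramework(cfg, spec, trainer, np.random.default_rng(0))
        batch = _batch(rng)
        d_before = [p.data.copy() for p in fw.D.parameters()]
        fw.opt_g.zero_grad()
        pix2pix_step(batch, fw.G, fw.D, cfg, "gen").backward()
        fw.opt_g.step()
        for before, p in zip(d_before, fw.D.parameters()):
            assert np.array_equal(before, p.data)
        g_before = [p.data.copy() for p in fw.G.parameters()]
        fw.opt_d.zero_grad()
        pix2pix_step(batch, fw.G, fw.D, cfg, "disc").backward()
        fw.opt_d.step()
        for before, p in zip(g_before, fw.G.parameters()):
            assert np.array_equal(before, p.data)

    def test_generator_init_reproduces_fcn_outputs_bitwise(self, rng, tmp_path):
        from im2im.trainer import save_checkpoint

        spec, trainer = _nets()
        fcn = FCNFramework(FrameworkConfig(kind="fcn"), spec, trainer,
                           np.random.default_rng(3))
        ckpt_path = tmp_path / "fcn.ckpt"
        save_checkpoint(ckpt_path, {"epoch": 0, "networks": fcn.state_dict(),
                                    "optimizers": {}})
        cfg = FrameworkConfig(kind="pix2pix", generator_init=str(ckpt_path))
        p2p = Pix2PixFramework(cfg, spec, trainer, np.random.default_rng(99))
        x = Tensor(rng.normal(size=(1, 1, 16, 16)).astype(np.float32))
        fcn.net.eval(), p2p.G.eval()
        assert np.array_equal(fcn.net(x).data, p2p.G(x).data)


class TestCycleGAN:
    def test_identity_generators_zero_cycle_and_identity(self, rng):
        cfg = FrameworkConfig(kind="cyclegan", adv_weight=0.0)
        a = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        b = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        loss = cyclegan_step(a, b, IdentityNet(), IdentityNet(), None, None,
                             cfg, "gen")
        assert loss.item() == pytest.approx(0.0, abs=1e-7)

    def test_constant_shift_closed_form_cycle(self):
        # both compositions shift constant images by +c -> cycle term = 2c
        c = 0.25
        cfg = FrameworkConfig(kind="cyclegan", adv_weight=0.0,
                              identity_weight=0.0, cycle_weight=1.0)
        a = np.zeros((1, 1, 4, 4), dtype=np.float32)
        b = np.zeros((1, 1, 4, 4), dtype=np.float32)
        loss = cyclegan_step(a, b, ShiftNet(c), IdentityNet(), None, None,
                             cfg, "gen")
        assert loss.item() == pytest.approx(2 * c, abs=1e-6)

    def test_all_losses_finite_with_default_config(self, rng):
        spec, trainer = _nets()
        cfg = FrameworkConfig(kind="cyclegan")
        fw = CycleGANFramework(cfg, spec, trainer, np.random.default_rng(0))
        a = rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32)
        b = rng.uniform(-1, 1, (1, 1, 16, 16)).astype(np.float32)
        for phase in ("gen", "disc"):
            loss = cyclegan_step(a, b, fw.G_AB, fw.G_BA, fw.D_A, fw.D_B, cfg, phase)
            assert np.isfinite(loss.item())


class TestBuildFramework:
    @pytest.mark.parametrize("kind", ["fcn", "pix2pix", "cyclegan", "embedseg"])
    def test_all_kinds_constructible(self, kind):
        spec = NetworkSpec(name="unet_2d", dim=2, in_channels=1,
                           out_channels=4 if kind == "embedseg" else 1,
                           depth=2, base_filters=4)
        fw = build_framework(FrameworkConfig(kind=kind), spec, TrainerConfig(),
                             np.random.default_rng(0))
        assert "generator" in fw.networks()
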