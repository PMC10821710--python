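"""Training-step logic for the image-regression frameworks.

Three frameworks share one data model:

* **FCN** — supervised per-pixel regression: masked reconstruction loss, one
  optimizer.
* **pix2pix** — FCN plus a conditional PatchGAN discriminator; generator loss
  ``λ_rec · recon + λ_adv · adv``, alternating generator/discriminator
  optimization. With ``λ_adv = 0`` the generator update reduces exactly to the
  FCN update. The generator can be pre-initialized from an FCN checkpoint.
* **CycleGAN** — unpaired two-domain translation with two generators and two
  discriminators; adversarial + cycle-consistency (+ optional identity)
  losses; both mapping directions are usable at inference.

GAN objectives: ``lsgan`` (squared error against 1/0 targets) or ``vanilla``
(log-sigmoid). Defaults λ_rec=100, λ_adv=1 (pix2pix); λ_cyc=10, λ_id=5
(CycleGAN) follow the originating conventions and are YAML-overridable.
"""

from __future__ import annotations

import numpy as np

from .core.config import FrameworkConfig, NetworkSpec, TrainerConfig
from .core.resolve import resolve_network
from .nn import Adam, Module, Tensor, concatenate
from .sampling import apply_exclusion

_F32 = np.float32


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def recon_loss_map(pred: Tensor, target: Tensor, kind: str) -> Tensor:
    diff = pred - target
    if kind == "mae":
        return diff.abs()
    if kind == "mse":
        return diff**2
    if kind == "smooth_mae":
        a = diff.abs()
        small = (a.data < 1.0).astype(_F32)  # branch choice, locally constant
        return (0.5 * diff**2) * small + (a - 0.5) * (1.0 - small)
    raise ValueError(f"unknown recon loss {kind!r}")


def adv_loss(logits: Tensor, real: bool, objective: str) -> Tensor:
    target = 1.0 if real else 0.0
    if objective == "lsgan":
        return ((logits.sigmoid() - target) ** 2).mean()
    if objective == "vanilla":
        p = logits.sigmoid().clamp(1e-6, 1.0 - 1e-6)
        return (-(p.log()) if real else -((1.0 - p).log())).mean()
    raise ValueError(f"unknown gan objective {objective!r}")


def fcn_step(batch, net: Module, cfg: FrameworkConfig) -> Tensor:
    """Masked reconstruction loss of net(source) against target."""
    source, target, mask = batch
    pred = net(Tensor(source))
    return apply_exclusion(recon_loss_map(pred, Tensor(target), cfg.recon_loss), mask)


def pix2pix_step(
    batch, G: Module, D: Module, cfg: FrameworkConfig, phase: str
) -> Tensor:
    source, target, mask = batch
    src_t = Tensor(source)
    if phase == "gen":
        fake = G(src_t)
        loss = cfg.recon_weight * apply_exclusion(
            recon_loss_map(fake, Tensor(target), cfg.recon_loss), mask
        )
        if cfg.adv_weight > 0:
            logits = D(concatenate([src_t, fake], axis=1))
            loss = loss + cfg.adv_weight * adv_loss(logits, True, cfg.gan_objective)
        return loss
    if phase == "disc":
        fake = G(src_t).detach()
        real_logits = D(concatenate([src_t, Tensor(target)], axis=1))
        fake_logits = D(concatenate([src_t, fake], axis=1))
        return 0.5 * (
            adv_loss(real_logits, True, cfg.gan_objective)
            + adv_loss(fake_logits, False, cfg.gan_objective)
        )
    raise ValueError(f"unknown phase {phase!r}")


def cyclegan_step(
    batch_a, batch_b, G_AB, G_BA, D_A, D_B, cfg: FrameworkConfig, phase: str
) -> Tensor:
    a = Tensor(batch_a)
    b = Tensor(batch_b)
    if phase == "gen":
        fake_b = G_AB(a)
        fake_a = G_BA(b)
        loss = cfg.cycle_weight * (
            (G_BA(fake_b) - a).abs().mean() + (G_AB(fake_a) - b).abs().mean()
        )
        if cfg.identity_weight > 0:
            loss = loss + cfg.identity_weight * (
                (G_AB(b) - b).abs().mean() + (G_BA(a) - a).abs().mean()
            )
        if cfg.adv_weight > 0:
            loss = loss + cfg.adv_weight * (
                adv_loss(D_B(fake_b), True, cfg.gan_objective)
                + adv_loss(D_A(fake_a), True, cfg.gan_objective)
            )
        return loss
    if phase == "disc":
        fake_b = G_AB(a).detach()
        fake_a = G_BA(b).detach()
        return 0.5 * (
            adv_loss(D_B(b), True, cfg.gan_objective)
            + adv_loss(D_B(fake_b), False, cfg.gan_objective)
            + adv_loss(D_A(a), True, cfg.gan_objective)
            + adv_loss(D_A(fake_a), False, cfg.gan_objective)
        )
    raise ValueError(f"unknown phase {phase!r}")


# ---------------------------------------------------------------------------
# framework drivers (network construction + optimizers + per-batch updates)
# ---------------------------------------------------------------------------

class Framework:
    """Owns networks and optimizers; one `training_step` per batch."""

    kind = "fcn"

    def __init__(self, cfg: FrameworkConfig, net_spec: NetworkSpec,
                 trainer: TrainerConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.net_spec = net_spec
        self.trainer = trainer
        self.rng = rng
        self.build()

    def build(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def networks(self) -> dict[str, Module]:
        raise NotImplementedError

    def predictor(self):
        """Numpy (1,C,*S)->(1,C',*S) callable for inference/validation."""
        net = self.networks()["generator"]

        def fn(x: np.ndarray) -> np.ndarray:
            net.eval()
            out = net(Tensor(x)).data
            net.train()
            return out

        return fn

    def state_dict(self):
        return {
            name: net.state_dict() for name, net in self.networks().items()
        }

    def load_state_dict(self, state):
        for name, net in self.networks().items():
            if name in state:
                net.load_state_dict(state[name])

    def _maybe_init_generator(self, gen: Module):
        if self.cfg.generator_init:
            from .trainer import load_checkpoint

            ckpt = load_checkpoint(self.cfg.generator_init)
            gen.load_state_dict(ckpt["networks"]["generator"])


class FCNFramework(Framework):
    kind = "fcn"

    def build(self):
        self.net = resolve_network(self.net_spec, self.rng)
        lr = self.trainer.lr_for("generator", 1e-3)
        self.opt = Adam(self.net.parameters(), lr=lr)

    def networks(self):
        return {"generator": self.net}

    def training_step(self, batch) -> dict[str, float]:
        self.opt.zero_grad()
        loss = fcn_step(batch, self.net, self.cfg)
        loss.backward()
        self.opt.step()
        return {"loss": loss.item()}


def _disc_spec(net_spec: NetworkSpec, in_channels: int) -> NetworkSpec:
    return NetworkSpec(
        name="patch_discriminator",
        dim=net_spec.dim,
        in_channels=in_channels,
        out_channels=1,
        base_filters=32,
        norm="batch",
    )


class Pix2PixFramework(Framework):
    kind = "pix2pix"

    def build(self):
        self.G = resolve_network(self.net_spec, self.rng)
        self._maybe_init_generator(self.G)
        d_in = self.net_spec.in_channels + self.net_spec.out_channels
        self.D = resolve_network(_disc_spec(self.net_spec, d_in), self.rng)
        self.opt_g = Adam(
            self.G.parameters(),
            lr=self.trainer.lr_for("generator", 2e-4),
            betas=(0.5, 0.999),
        )
        self.opt_d = Adam(
            self.D.parameters(),
            lr=self.trainer.lr_for("discriminator", 2e-4),
            betas=(0.5, 0.999),
        )

    def networks(self):
        return {"generator": self.G, "discriminator": self.D}

    def training_step(self, batch) -> dict[str, float]:
        self.opt_g.zero_grad()
        g_loss = pix2pix_step(batch, self.G, self.D, self.cfg, "gen")
        g_loss.backward()
        self.opt_g.step()
        logs = {"g_loss": g_loss.item()}
        if self.cfg.adv_weight > 0:
            self.opt_d.zero_grad()
            d_loss = pix2pix_step(batch, self.G, self.D, self.cfg, "disc")
            d_loss.backward()
            self.opt_d.step()
            logs["d_loss"] = d_loss.item()
        logs["loss"] = logs["g_loss"]
        return logs


class CycleGANFramework(Framework):
    kind = "cyclegan"

    def build(self):
        spec_ab = self.net_spec
        spec_ba = self.net_spec.model_copy(
            update={
                "in_channels": self.net_spec.out_channels,
                "out_channels": self.net_spec.in_channels,
            }
        )
        self.G_AB = resolve_network(spec_ab, self.rng)
        self.G_BA = resolve_network(spec_ba, self.rng)
        self.D_A = resolve_network(
            _disc_spec(spec_ab, self.net_spec.in_channels), self.rng
        )
        self.D_B = resolve_network(
            _disc_spec(spec_ab, self.net_spec.out_channels), self.rng
        )
        gen_params = list(self.G_AB.parameters()) + list(self.G_BA.parameters())
        disc_params = list(self.D_A.parameters()) + list(self.D_B.parameters())
        self.opt_g = Adam(
            gen_params, lr=self.trainer.lr_for("generator", 2e-4), betas=(0.5, 0.999)
        )
        self.opt_d = Adam(
            disc_params,
            lr=self.trainer.lr_for("discriminator", 2e-4),
            betas=(0.5, 0.999),
        )

    def networks(self):
        return {
            "generator": self.G_AB,
            "generator_ba": self.G_BA,
            "discriminator_a": self.D_A,
            "discriminator_b": self.D_B,
        }

    def training_step(self, batch) -> dict[str, float]:
        # unpaired: source batch is domain A, target batch domain B
        a, b, _ = batch
        self.opt_g.zero_grad()
        g_loss = cyclegan_step(
            a, b, self.G_AB, self.G_BA, self.D_A, self.D_B, self.cfg, "gen"
        )
        g_loss.backward()
        self.opt_g.step()
        self.opt_d.zero_grad()
        d_loss = cyclegan_step(
            a, b, self.G_AB, self.G_BA, self.D_A, self.D_B, self.cfg, "disc"
        )
        d_loss.backward()
        self.opt_d.step()
        return {"loss": g_loss.item(), "g_loss": g_loss.item(), "d_loss": d_loss.item()}


def build_framework(
    cfg: FrameworkConfig,
    net_spec: NetworkSpec,
    trainer: TrainerConfig,
    rng: np.random.Generator,
) -> Framework:
    from .embedseg import EmbedSegFramework

    cls = {
        "fcn": FCNFramework,
        "pix2pix": Pix2PixFramework,
        "cyclegan": CycleGANFramework,
        "embedseg": EmbedSegFramework,
    }[cfg.kind]
    return cls(cfg, net_spec, trainer, rng)
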