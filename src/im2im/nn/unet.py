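"""Built-in backbones: dimension-generic U-Net (isotropic or anisotropic) and a
PatchGAN-style discriminator.

The U-Net is written once for 2D and 3D. Anisotropy is expressed through
per-transition, per-axis down factors: a transition with factor 1 along Z
neither downsamples nor convolves along Z (flat-Z 1×3×3 kernels), which lets
volumes with few Z slices pass through deep networks — the standard trick for
microscopy stacks whose axial extent is far smaller than their lateral extent.

``depth`` counts resolution levels, so a network of depth ``L`` applies
``L - 1`` down transitions and ``down_factors`` has ``L - 1`` entries.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate
from .layers import Activation, ConvNd, Module, Sequential, make_norm


def _conv_block(dim, in_ch, out_ch, norm, rng, kernel=None):
    kernel = kernel if kernel is not None else (3,) * dim
    return Sequential(
        ConvNd(dim, in_ch, out_ch, kernel, rng),
        make_norm(norm, out_ch),
        Activation("relu"),
        ConvNd(dim, out_ch, out_ch, kernel, rng),
        make_norm(norm, out_ch),
        Activation("relu"),
    )


class UNet(Module):
    """Encoder-decoder with skip connections and configurable per-axis strides.

    Parameters
    ----------
    dim : 2 or 3
    depth : number of resolution levels (>= 1); 1 means plain conv blocks.
    down_factors : optional list of ``depth - 1`` per-axis factor tuples;
        defaults to isotropic 2s.
    """

    def __init__(
        self,
        dim: int,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        depth: int = 3,
        base_filters: int = 16,
        down_factors=None,
        norm: str = "instance",
        final_activation: str = "none",
    ):
        super().__init__()
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.dim = dim
        if down_factors is None:
            down_factors = [(2,) * dim for _ in range(depth - 1)]
        down_factors = [tuple(int(f) for f in fs) for fs in down_factors]
        if len(down_factors) != depth - 1:
            raise ValueError(
                f"down_factors needs {depth - 1} entries for depth {depth}, "
                f"got {len(down_factors)}"
            )
        for fs in down_factors:
            if len(fs) != dim:
                raise ValueError("each down factor needs one entry per spatial axis")
        self.down_factors = down_factors

        chans = [base_filters * 2**i for i in range(depth)]

        def level_kernel(fs):
            # flat kernels along axes that are not downsampled at this level
            return tuple(1 if f == 1 and dim == 3 and a == 0 else 3 for a, f in enumerate(fs))

        self.enc = [_conv_block(dim, in_channels, chans[0], norm, rng)]
        self.down = []
        for i in range(depth - 1):
            fs = down_factors[i]
            self.down.append(
                ConvNd(dim, chans[i], chans[i + 1], fs, rng, stride=fs, padding=0)
            )
            self.enc.append(
                _conv_block(dim, chans[i + 1], chans[i + 1], norm, rng, level_kernel(fs))
            )
        self.up = []
        self.dec = []
        for i in reversed(range(depth - 1)):
            fs = down_factors[i]
            self.up.append(ConvNd(dim, chans[i + 1], chans[i], (1,) * dim, rng))
            self.dec.append(
                _conv_block(dim, chans[i] * 2, chans[i], norm, rng, level_kernel(fs))
            )
        self.head = ConvNd(dim, chans[0], out_channels, (1,) * dim, rng)
        self.final_activation = Activation(final_activation)
        self.out_channels = out_channels
        self.in_channels = in_channels

    @property
    def total_down_factor(self):
        """Per-axis product of all down factors (divisibility contract)."""
        total = [1] * self.dim
        for fs in self.down_factors:
            for a, f in enumerate(fs):
                total[a] *= f
        return tuple(total)

    def _check_shape(self, x: Tensor):
        spatial = x.shape[2:]
        for a, (s, f) in enumerate(zip(spatial, self.total_down_factor)):
            if s % f != 0:
                axis = ("Z", "Y", "X")[a + (3 - self.dim)]
                raise ValueError(
                    f"spatial axis {axis} has extent {s}, not divisible by the "
                    f"network's total down factor {f}"
                )

    def forward(self, x: Tensor) -> Tensor:
        self._check_shape(x)
        skips = []
        h = self.enc[0](x)
        for i, down in enumerate(self.down):
            skips.append(h)
            h = down(h)
            h = self.enc[i + 1](h)
        for j, (up, dec) in enumerate(zip(self.up, self.dec)):
            i = len(self.down) - 1 - j
            h = h.upsample_nearest(self.down_factors[i])
            h = up(h)
            h = concatenate([skips[i], h], axis=1)
            h = dec(h)
        return self.final_activation(self.head(h))


class PatchDiscriminator(Module):
    """PatchGAN discriminator: a grid of real/fake logits, one per receptive field.

    ``n_blocks`` stride-2 blocks shrink each spatial axis by ``2**n_blocks``.
    For conditional (pix2pix) use, concatenate source and candidate on channels
    before calling.
    """

    def __init__(
        self,
        dim: int,
        in_channels: int,
        rng: np.random.Generator,
        base_filters: int = 32,
        n_blocks: int = 3,
        norm: str = "batch",
    ):
        super().__init__()
        self.dim = dim
        self.in_channels = in_channels
        mods = []
        ch = in_channels
        nxt = base_filters
        for b in range(n_blocks):
            mods.append(ConvNd(dim, ch, nxt, (4,) * dim, rng, stride=2, padding=1))
            if b > 0:
                mods.append(make_norm(norm, nxt))
            mods.append(Activation("leaky_relu"))
            ch, nxt = nxt, min(nxt * 2, 256)
        mods.append(ConvNd(dim, ch, 1, (3,) * dim, rng))
        self.body = Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)
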