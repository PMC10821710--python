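"""Network resolution: built-in backbones by name, anything else by dotted import.

``resolve_network`` instantiates a backbone from a :class:`NetworkSpec` and
verifies its shape contract with a probe tensor — a forward pass on a minimal
valid input must return the declared number of output channels with spatial
shape preserved (generators) before the network is accepted.
"""

from __future__ import annotations

import importlib

import numpy as np

from ..nn import PatchDiscriminator, Tensor, UNet
from .config import NetworkSpec

BUILTIN_NAMES = ("unet_2d", "unet_3d", "unet_aniso_3d", "patch_discriminator")


class NetworkResolutionError(ValueError):
    pass


def _import_dotted(path: str):
    module_path, _, symbol = path.rpartition(".")
    if not module_path:
        raise NetworkResolutionError(f"not a dotted import path: {path!r}")
    try:
        mod = importlib.import_module(module_path)
    except ImportError as err:
        raise NetworkResolutionError(f"cannot import {module_path!r}: {err}") from None
    try:
        return getattr(mod, symbol)
    except AttributeError:
        raise NetworkResolutionError(
            f"module {module_path!r} has no attribute {symbol!r}"
        ) from None


def _build_builtin(spec: NetworkSpec, rng: np.random.Generator):
    if spec.name in ("unet_2d", "unet_3d", "unet_aniso_3d"):
        dim = 2 if spec.name == "unet_2d" else 3
        if spec.dim != dim:
            raise NetworkResolutionError(
                f"{spec.name} requires dim={dim}, spec says dim={spec.dim}"
            )
        return UNet(
            dim=dim,
            in_channels=spec.in_channels,
            out_channels=spec.out_channels,
            rng=rng,
            depth=spec.depth,
            base_filters=spec.base_filters,
            down_factors=spec.down_factors,
            norm=spec.norm,
            final_activation=spec.final_activation,
        )
    if spec.name == "patch_discriminator":
        return PatchDiscriminator(
            dim=spec.dim,
            in_channels=spec.in_channels,
            rng=rng,
            base_filters=spec.base_filters,
            norm=spec.norm if spec.norm != "instance" else "batch",
            **spec.kwargs,
        )
    raise NetworkResolutionError(f"unknown builtin {spec.name!r}")


def probe_shape(spec: NetworkSpec) -> tuple[int, ...]:
    """Minimal valid input shape for the spec (batch 1)."""
    if spec.name in BUILTIN_NAMES and spec.name != "patch_discriminator":
        factors = [1] * spec.dim
        if spec.down_factors:
            for fs in spec.down_factors:
                for a, f in enumerate(fs):
                    factors[a] *= f
        else:
            factors = [2 ** (spec.depth - 1)] * spec.dim
        spatial = tuple(max(f, 8) if f > 1 else 8 for f in factors)
        # extents must be divisible by the factor product
        spatial = tuple(-(-s // f) * f for s, f in zip(spatial, factors))
    else:
        spatial = (16,) * spec.dim
    return (1, spec.in_channels) + spatial


def resolve_network(spec: NetworkSpec, rng: np.random.Generator | None = None):
    """Instantiate the network named by ``spec`` and shape-check it.

    Built-in names resolve to the package backbones; any other name is treated
    as a dotted import path called with ``spec.kwargs``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    if spec.name in BUILTIN_NAMES:
        net = _build_builtin(spec, rng)
    else:
        factory = _import_dotted(spec.name)
        try:
            net = factory(**spec.kwargs)
        except TypeError as err:
            raise NetworkResolutionError(
                f"calling {spec.name!r} with kwargs {spec.kwargs} failed: {err}"
            ) from None

    probe = Tensor(np.zeros(probe_shape(spec), dtype=np.float32))
    try:
        out = net(probe)
    except Exception as err:
        raise NetworkResolutionError(
            f"network {spec.name!r} failed on probe input of shape "
            f"{probe.shape}: {err}"
        ) from None
    out_shape = out.shape if hasattr(out, "shape") else np.shape(out)
    if out_shape[1] != spec.out_channels:
        raise NetworkResolutionError(
            f"shape contract violated: expected {spec.out_channels} output "
            f"channels, got {out_shape[1]} (output shape {tuple(out_shape)})"
        )
    return net
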