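"""Neural-network building blocks over the autograd engine.

Modules follow the familiar container convention: submodules assigned as
attributes are discovered automatically, ``state_dict`` / ``load_state_dict``
move plain numpy arrays, and ``train()`` / ``eval()`` toggle the normalization
behaviour. Weight initialization takes an explicit ``numpy.random.Generator``
so that two builds with the same seed are bitwise identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

_F32 = np.float32


class Module:
    def __init__(self):
        self.training = True

    # -- discovery ---------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- mode --------------------------------------------------------------
    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({"buffer:" + k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for key, val in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                self._set_buffer(name, val)
            else:
                if key not in params:
                    raise KeyError(f"unknown parameter {key!r} in state dict")
                if params[key].data.shape != val.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: "
                        f"{params[key].data.shape} vs {val.shape}"
                    )
                params[key].data = np.asarray(val, dtype=_F32).copy()

    def _set_buffer(self, dotted: str, val: np.ndarray):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)] if isinstance(obj, (list, tuple)) else getattr(obj, part)
            else:
                attr = getattr(obj, part)
                obj = attr
        leaf = parts[-1]
        if isinstance(obj, Module) and isinstance(getattr(obj, leaf, None), np.ndarray):
            setattr(obj, leaf, np.asarray(val).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ConvNd(Module):
    """N-d convolution (cross-correlation) with He-normal init."""

    def __init__(self, dim, in_ch, out_ch, kernel, rng, stride=1, padding="same", bias=True):
        super().__init__()
        kernel = (kernel,) * dim if isinstance(kernel, int) else tuple(kernel)
        stride = (stride,) * dim if isinstance(stride, int) else tuple(stride)
        if padding == "same":
            padding = tuple(k // 2 for k in kernel)
        elif isinstance(padding, int):
            padding = (padding,) * dim
        self.stride = stride
        self.padding = tuple(padding)
        fan_in = in_ch * int(np.prod(kernel))
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch) + kernel) * scale, requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv(self.weight, self.bias, self.stride, self.padding)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over spatial axes with affine params."""

    def __init__(self, num_ch: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(num_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        d = x.ndim - 2
        axes = tuple(range(2, 2 + d))
        m = x.mean(axis=axes, keepdims=True)
        v = ((x - m) ** 2).mean(axis=axes, keepdims=True)
        shape = (1, -1) + (1,) * d
        xn = (x - m) / ((v + self.eps) ** 0.5)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm(Module):
    """Batch normalization with running statistics for eval mode."""

    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(num_ch), requires_grad=True)
        self.running_mean = np.zeros(num_ch, dtype=_F32)
        self.running_var = np.ones(num_ch, dtype=_F32)

    def forward(self, x: Tensor) -> Tensor:
        d = x.ndim - 2
        axes = (0,) + tuple(range(2, 2 + d))
        shape = (1, -1) + (1,) * d
        if self.training:
            m = x.mean(axis=axes, keepdims=True)
            v = ((x - m) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * m.data.reshape(-1)
            ).astype(_F32)
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * v.data.reshape(-1)
            ).astype(_F32)
        else:
            m = Tensor(self.running_mean.reshape(shape))
            v = Tensor(self.running_var.reshape(shape))
        xn = (x - m) / ((v + self.eps) ** 0.5)
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Activation(Module):
    def __init__(self, kind: str):
        super().__init__()
        self.kind = kind

    def forward(self, x: Tensor) -> Tensor:
        if self.kind == "relu":
            return x.relu()
        if self.kind == "leaky_relu":
            return x.leaky_relu(0.2)
        if self.kind == "tanh":
            return x.tanh()
        if self.kind == "sigmoid":
            return x.sigmoid()
        if self.kind == "none":
            return x
        raise ValueError(f"unknown activation {self.kind!r}")


def make_norm(kind: str, ch: int) -> Module:
    if kind == "instance":
        return InstanceNorm(ch)
    if kind == "batch":
        return BatchNorm(ch)
    if kind == "none":
        return Activation("none")
    raise ValueError(f"unknown norm {kind!r}")


class Adam:
    """Adam optimizer; one instance owns one parameter group."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                _F32
            )

    def state_dict(self):
        return {"t": self.t, "m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(a, dtype=_F32) for a in state["m"]]
        self.v = [np.asarray(a, dtype=_F32) for a in state["v"]]
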