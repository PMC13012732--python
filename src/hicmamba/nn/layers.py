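"""Parameter containers and layers built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, conv2d, down2x2, up2x2

DTYPE = np.float32


class Module:
    """Tiny module tree with named-parameter traversal for checkpointing."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_modules", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(DTYPE), requires_grad=True)


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True,
                 init_scale: float = 1.0, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = glorot(rng, (d_in, d_out), d_in, d_out) * init_scale
        self.weight = _param(w)
        self.bias = _param(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """Stride-1 same-padding convolution (kernel 1 or 3 in this package)."""

    def __init__(self, rng, c_in: int, c_out: int, k: int, zero_init: bool = False,
                 init_scale: float = 1.0):
        super().__init__()
        fan_in, fan_out = c_in * k * k, c_out * k * k
        w = np.zeros((c_out, c_in, k, k)) if zero_init else glorot(
            rng, (c_out, c_in, k, k), fan_in, fan_out) * init_scale
        self.weight = _param(w)
        self.bias = _param(np.zeros(c_out))
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, pad=self.k // 2)
        return y + self.bias.reshape(1, -1, 1, 1)


class Downsample(Module):
    """2x2 stride-2 convolution doubling the channel count."""

    def __init__(self, rng, c_in: int, c_out: int):
        super().__init__()
        self.weight = _param(glorot(rng, (c_out, c_in, 2, 2), c_in * 4, c_out * 4))
        self.bias = _param(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return down2x2(x, self.weight) + self.bias.reshape(1, -1, 1, 1)


class Upsample(Module):
    """2x2 stride-2 transposed convolution halving the channel count."""

    def __init__(self, rng, c_in: int, c_out: int):
        super().__init__()
        self.weight = _param(glorot(rng, (c_in, c_out, 2, 2), c_in * 4, c_out * 4))
        self.bias = _param(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return up2x2(x, self.weight) + self.bias.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Normalizes over the channel axis of a (B, C, H, W) feature map."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Adam:
    """Adam optimizer with optional global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 1.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.t = 0

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            step = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data.astype(np.float64) - step).astype(p.data.dtype)


__all__ = ["Module", "Linear", "Conv2d", "Downsample", "Upsample", "LayerNorm",
           "Adam", "Tensor", "concatenate", "DTYPE", "glorot"]
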