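"""Minimal neural-network layer set for 3D volumes.

Built on :mod:`brainmga.autodiff`.  Convolution and max pooling are
implemented as flat gather (im2col) followed by matmul / max, so both
forward and backward reduce to BLAS calls plus one scatter-add.  Only what
the brain-age network needs is provided: Conv3d, BatchNorm3d, MaxPool3d,
Linear, global average pooling, and an Adam optimizer with L2 weight decay.

All parameters are float32 for speed; statistics inside BatchNorm are
accumulated in float32 as well, which is ample at desk-scale batch sizes.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv3d",
    "BatchNorm3d",
    "MaxPool3d",
    "Linear",
    "global_avg_pool",
    "Adam",
]

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)
        self.requires_grad = True  # parameters are trainable even under no_grad


class Module:
    """Base class with recursive parameter/buffer discovery by attribute name."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ----------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> list:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------------

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(DTYPE)
            elif kind == "buffer":
                obj = self
                *path, attr = name.split(".")
                for part in path:
                    obj = getattr(obj, part)
                getattr(obj, attr)  # attribute must exist
                setattr(obj, attr, value.copy())
        missing = set(params) - {
            k.partition(":")[2] for k in state if k.startswith("param:")
        }
        if missing:
            raise KeyError(f"checkpoint is missing parameters: {sorted(missing)}")


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)
        self._n = len(tuple(modules))

    def __iter__(self):
        return (getattr(self, str(i)) for i in range(self._n))

    def __len__(self):
        return self._n

    def __getitem__(self, i):
        return getattr(self, str(i))

    def append(self, m: Module) -> None:
        setattr(self, str(self._n), m)
        self._n += 1


# ---------------------------------------------------------------------------
# im2col machinery (shared by Conv3d and MaxPool3d)
# ---------------------------------------------------------------------------

_INDEX_CACHE: dict = {}


def _window_index(shape, kernel, stride, channels_in_window):
    """Flat gather indices for sliding 3D windows over a padded volume.

    shape: padded per-item shape (C, H, W, D).  Returns (idx, out_extent)
    with idx of shape (L, K): L output positions, K window entries
    (K = C·k³ when channels are inside the window, k³ otherwise).
    """
    key = (shape, kernel, stride, channels_in_window)
    hit = _INDEX_CACHE.get(key)
    if hit is not None:
        return hit
    C, H, W, D = shape
    k = kernel
    oh = (H - k) // stride + 1
    ow = (W - k) // stride + 1
    od = (D - k) // stride + 1
    if channels_in_window:
        c, kh, kw, kd = np.meshgrid(
            np.arange(C), np.arange(k), np.arange(k), np.arange(k), indexing="ij"
        )
        base = ((((c * H) + kh) * W + kw) * D + kd).reshape(-1)
    else:
        kh, kw, kd = np.meshgrid(np.arange(k), np.arange(k), np.arange(k), indexing="ij")
        base = (((kh * W) + kw) * D + kd).reshape(-1)
    gh, gw, gd = np.meshgrid(
        np.arange(oh) * stride, np.arange(ow) * stride, np.arange(od) * stride,
        indexing="ij",
    )
    origins = (((gh * W) + gw) * D + gd).reshape(-1)
    idx = (origins[:, None] + base[None, :]).astype(np.int64)
    result = (idx, (oh, ow, od))
    _INDEX_CACHE[key] = result
    return result


def _batched_index(idx: np.ndarray, n: int, item_size: int) -> np.ndarray:
    # keyed on id(idx): window index arrays live forever in _INDEX_CACHE
    key = ("batched", id(idx), n, item_size)
    hit = _INDEX_CACHE.get(key)
    if hit is not None:
        return hit
    out = (np.arange(n, dtype=np.int64) * item_size)[:, None, None] + idx[None]
    _INDEX_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv3d(Module):
    """3D convolution via im2col; He-normal weight init."""

    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           (out_channels, fan_in)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p = self.padding
        if p:
            x = ad.pad_nd(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        padded = x.shape[1:]
        idx, out_ext = _window_index(padded, self.kernel, self.stride, True)
        bidx = _batched_index(idx, n, int(np.prod(padded)))
        cols = ad.take_flat(x, bidx)  # (N, L, K)
        out = ad.matmul(cols, self.weight.swapaxes(0, 1))  # (N, L, Cout)
        if self.bias is not None:
            out = out + self.bias
        out = out.transpose((0, 2, 1))
        return out.reshape((n, self.out_channels) + out_ext)


class BatchNorm3d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, self.channels, 1, 1, 1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(-1).astype(DTYPE))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1).astype(DTYPE))
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mean = self.running_mean.reshape(shape)
            inv = 1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mean) * inv
        return xhat * self.weight.reshape(shape) + self.bias.reshape(shape)


class MaxPool3d(Module):
    def __init__(self, kernel, stride, padding=0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        flat = x.reshape((n * c, 1) + spatial)
        p = self.padding
        if p:
            # pad with a large negative value so padding never wins the max
            flat = ad.pad_nd(flat, ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
                             value=-1e30)
        padded = flat.shape[1:]
        idx, out_ext = _window_index(padded, self.kernel, self.stride, False)
        bidx = _batched_index(idx, n * c, int(np.prod(padded)))
        windows = ad.take_flat(flat, bidx)  # (N*C, L, k^3)
        pooled = windows.max(axis=2)
        return pooled.reshape((n, c) + out_ext)


class Linear(Module):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight.swapaxes(0, 1)) + self.bias


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W, D) → (N, C) spatial mean."""
    return x.mean(axis=(2, 3, 4))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=0.005, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0001):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
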