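"""Layers with explicit forward/backward passes.

Tensors are float32 arrays in NCHW layout.  Every layer caches what its
backward pass needs during forward; ``backward(grad_out)`` returns the
gradient with respect to the layer input and accumulates parameter gradients
in place.  Convolution is evaluated as k*k strided matmuls (one per kernel
offset), which is both simple and fast for the 3x3/1x1 kernels used here.
"""
from __future__ import annotations

from typing import List, Optional

import numpy as np


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data.astype(np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    def params(self) -> List[Param]:
        out: List[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def modules(self) -> List["Module"]:
        out: List[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def set_training(self, training: bool) -> None:
        for m in self.modules():
            m.training = training

    def state(self) -> List[np.ndarray]:
        out = [p.data.copy() for p in self.params()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                out.extend([m.running_mean.copy(), m.running_var.copy()])
        return out

    def load_state(self, state: List[np.ndarray]) -> None:
        own = self.params()
        slots = [p.data for p in own]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                slots.extend([m.running_mean, m.running_var])
        if len(slots) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(slots)}")
        for dst, arr in zip(slots, state):
            dst[...] = np.asarray(arr, dtype=np.float32).reshape(dst.shape)


class Conv2d(Module):
    """3x3 (or 1x1) convolution, stride 1 or 2, 'same' padding for k=3."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 rng: Optional[np.random.Generator] = None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        self.k, self.stride = k, stride
        self.pad = k // 2
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(out_ch, in_ch, k, k)).astype(np.float32))
        self.b = Param(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self._xp_shape = None
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        out = np.zeros((n, self.W.data.shape[0], ho, wo),
                       dtype=np.result_type(xp.dtype, self.W.data.dtype))
        Wd = self.W.data
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di:di + s * ho:s, dj:dj + s * wo:s]
                # (N,C,Ho,Wo) x (O,C) -> (N,O,Ho,Wo)
                out += np.einsum("oc,nchw->nohw", Wd[:, :, di, dj], xs, optimize=True)
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, c, hp, wp = xp.shape
        k, s, p = self.k, self.stride, self.pad
        ho, wo = g.shape[2], g.shape[3]
        dxp = np.zeros_like(xp)
        Wd = self.W.data
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di:di + s * ho:s, dj:dj + s * wo:s]
                self.W.grad[:, :, di, dj] += np.einsum("nohw,nchw->oc", g, xs, optimize=True)
                dxp[:, :, di:di + s * ho:s, dj:dj + s * wo:s] += np.einsum(
                    "oc,nohw->nchw", Wd[:, :, di, dj], g, optimize=True)
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2, 3))
        self._xp = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with learned scale/shift.

    Uses batch statistics while ``training`` is True and exponential running
    averages at inference.  Running stats are saved as part of the model
    state, after the trainable parameters.
    """

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch, dtype=np.float32))
        self.beta = Param(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gxhat = g * self.gamma.data[None, :, None, None]
        if self.training:
            sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - sum_g / n - xhat * sum_gx / n) * inv[None, :, None, None]
        else:
            gx = gxhat * inv[None, :, None, None]
        self._cache = None
        return gx.astype(xhat.dtype)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn with identity (or projected) shortcut, relu after add."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, rng, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, rng, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride, rng, bias=False)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None
            self.proj_bn = None
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x))
        else:
            sc = x
        return self.relu2.forward(y + sc)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(g)
        gx = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(g)))))
        if self.proj is not None:
            gx += self.proj.backward(self.proj_bn.backward(g))
        else:
            gx += g
        return gx


class UpsampleNearest(Module):
    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, h, w = g.shape
        return g.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(g[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / in_f),
                                  size=(out_f, in_f)).astype(np.float32))
        self.b = Param(np.zeros(out_f, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        out = g @ self.W.data
        self._x = None
        return out
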