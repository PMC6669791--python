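"""Minimal define-by-run automatic differentiation for 3-D convolutional nets.

All arrays are float32 with layout ``(N, C, X, Y, Z)``.  Convolutions are
evaluated as a loop over kernel taps, each tap a batched BLAS matmul, which
keeps peak memory far below an im2col buffer while remaining fast for the
filter widths used here.

The surface is deliberately small: :class:`Tensor` with reverse-mode
backprop, :class:`Module` with parameter registration and a flat
``state_dict``, the layers needed by the segmentation networks, and the
Nesterov-Adam optimizer used for training.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "PReLU",
    "ReLU",
    "Dropout",
    "Sigmoid",
    "MaxPool3d",
    "Upsample3d",
    "Sequential",
    "add",
    "concat",
    "pad_spatial",
    "crop_spatial",
    "sigmoid",
    "soft_jaccard_loss",
    "NesterovAdam",
    "he_uniform",
]


# ---------------------------------------------------------------------------
# Tensor and reverse-mode autodiff
# ---------------------------------------------------------------------------

class Tensor:
    """An array plus the closure that propagates gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def _unary(x: Tensor, out: np.ndarray, dfn: Callable[[np.ndarray], np.ndarray]) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(dfn(g))
    return Tensor(out, parents=(x,), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g)
        if b.requires_grad:
            b.accumulate_grad(g)
    return Tensor(a.data + b.data, parents=(a, b), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)
    def backward(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(sl)])
    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def pad_spatial(x: Tensor, pads: tuple[tuple[int, int], ...]) -> Tensor:
    """Zero-pad the three trailing spatial axes; ``pads`` is ((lo,hi),)*3."""
    full = ((0, 0), (0, 0)) + tuple(pads)
    out = np.pad(x.data, full)
    sl = tuple(slice(lo, out.shape[i] - hi) for i, (lo, hi) in enumerate(full))
    def backward(g):
        if x.requires_grad:
            x.accumulate_grad(g[sl])
    return Tensor(out, parents=(x,), backward=backward)


def crop_spatial(x: Tensor, crops: tuple[tuple[int, int], ...]) -> Tensor:
    """Crop the three trailing spatial axes; inverse of :func:`pad_spatial`."""
    full = ((0, 0), (0, 0)) + tuple(crops)
    sl = tuple(slice(lo, x.shape[i] - hi) for i, (lo, hi) in enumerate(full))
    out = x.data[sl]
    def backward(g):
        if x.requires_grad:
            buf = np.zeros_like(x.data)
            buf[sl] = g
            x.accumulate_grad(buf)
    return Tensor(out, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    d = x.data
    out = np.empty_like(d)
    pos = d >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ex = np.exp(d[~pos])
    out[~pos] = ex / (1.0 + ex)
    return _unary(x, out, lambda g: g * out * (1.0 - out))


def soft_jaccard_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-5) -> Tensor:
    """Differentiable Jaccard loss ``1 - (|X∩Y|+eps)/(|X∪Y|+eps)``.

    ``pred`` holds per-voxel foreground probabilities, ``target`` the 0/1
    reference.  The soft intersection is ``sum(p*y)`` and the soft union
    ``sum(p)+sum(y)-sum(p*y)``; the loss is averaged over batch items and
    channels (axes 0 and 1 when present), so a multi-organ head contributes
    one equally-weighted term per organ.
    """
    y = np.asarray(target, dtype=np.float32)
    p = pred.data
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != target shape {y.shape}")
    if p.ndim >= 3:
        red = tuple(range(p.ndim - 3, p.ndim))
    else:
        red = tuple(range(p.ndim))
    inter = (p * y).sum(axis=red)
    union = p.sum(axis=red) + y.sum(axis=red) - inter
    r = (inter + eps) / (union + eps)
    loss = float(np.mean(1.0 - r))
    n_terms = max(r.size, 1)

    def backward(g):
        if pred.requires_grad:
            gi = np.asarray(g, dtype=np.float32).reshape(())
            denom = (union + eps)
            # d r / d p = (y*(U+eps) - (I+eps)*(1-y)) / (U+eps)^2
            a = np.reshape(denom, denom.shape + (1,) * len(red))
            b = np.reshape(inter + eps, a.shape)
            dr = (y * a - b * (1.0 - y)) / (a * a)
            pred.accumulate_grad(-gi * dr / n_terms)

    return Tensor(np.float32(loss), parents=(pred,), backward=backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator["Parameter"]:
        for p in self._params.values():
            yield p
        for m in self._mods.values():
            yield from m.parameters()

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for name, m in self._mods.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=np.float32).copy()
        for name in self._buffers:
            self._buffers[name][...] = np.asarray(state[prefix + name])
        for name, m in self._mods.items():
            m.load_state_dict(state, prefix + name + ".")

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3d(Module):
    """3-D convolution (cross-correlation) with cubic kernel.

    Weight layout ``(C_out, C_in, k, k, k)``; supports arbitrary integer
    stride and symmetric zero padding, covering the 3x3x3 padded blocks, the
    2x2x2 stride-2 pooling convolutions and the valid convolutions of the
    baseline U-Net.
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, padding=0, *, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = c_in * kernel ** 3
        self.weight = Parameter(he_uniform(rng, (c_out, c_in, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        k, s, p = self.kernel, self.stride, self.padding
        return tuple((d + 2 * p - k) // s + 1 for d in spatial)  # type: ignore

    def _tap_slices(self, out_sp):
        k, s = self.kernel, self.stride
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    yield (i, j, l), (
                        slice(None), slice(None),
                        slice(i, i + s * (out_sp[0] - 1) + 1, s),
                        slice(j, j + s * (out_sp[1] - 1) + 1, s),
                        slice(l, l + s * (out_sp[2] - 1) + 1, s),
                    )

    def forward(self, x: Tensor) -> Tensor:
        # Only the padded input is retained for backward; tap windows are
        # re-sliced there, keeping peak memory at one volume per layer.
        k, s, p = self.kernel, self.stride, self.padding
        w, b = self.weight, self.bias
        xp = np.pad(x.data, ((0, 0), (0, 0)) + ((p, p),) * 3) if p else x.data
        N = xp.shape[0]
        out_sp = tuple((d - k) // s + 1 for d in xp.shape[2:])
        if any(d < 1 for d in out_sp):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} too small for kernel {k} "
                f"(minimum {k - 2 * p} per axis)"
            )
        V = int(np.prod(out_sp))
        w_taps = np.ascontiguousarray(
            w.data.reshape(self.c_out, self.c_in, k ** 3).transpose(2, 0, 1)
        )
        y = np.zeros((N, self.c_out, V), dtype=np.float32)
        for t, ((i, j, l), sl) in enumerate(self._tap_slices(out_sp)):
            xs = np.ascontiguousarray(xp[sl]).reshape(N, self.c_in, V)
            y += np.matmul(w_taps[t], xs)
        y += b.data[None, :, None]
        out = y.reshape(N, self.c_out, *out_sp)

        def backward(g):
            gmat = np.ascontiguousarray(g).reshape(N, self.c_out, V)
            if b.requires_grad:
                b.accumulate_grad(gmat.sum(axis=(0, 2)))
            if w.requires_grad and w.grad is None:
                w.grad = np.zeros_like(w.data)
            dxp = np.zeros(xp.shape, dtype=np.float32) if x.requires_grad else None
            for (i, j, l), sl in self._tap_slices(out_sp):
                if w.requires_grad:
                    xs = np.ascontiguousarray(xp[sl]).reshape(N, self.c_in, V)
                    w.grad[:, :, i, j, l] += np.einsum(
                        "nov,ncv->oc", gmat, xs, optimize=True
                    )
                if dxp is not None:
                    dxp[sl] += np.matmul(w.data[:, :, i, j, l].T, gmat).reshape(
                        N, self.c_in, *out_sp
                    )
            if dxp is not None:
                if p:
                    dxp = dxp[:, :, p:-p, p:-p, p:-p]
                x.accumulate_grad(dxp)

        return Tensor(out, parents=(x, w, b), backward=backward)


class ConvTranspose3d(Module):
    """Transpose convolution with kernel 2 and stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in, c_out, *, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(he_uniform(rng, (c_out, c_in, 2, 2, 2), c_in * 8))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        N, C = x.shape[:2]
        sx, sy, sz = x.shape[2:]
        V = sx * sy * sz
        xin = x.data.reshape(N, C, V)
        out = np.zeros((N, self.c_out, 2 * sx, 2 * sy, 2 * sz), dtype=np.float32)
        slices = {}
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    sl = (slice(None), slice(None), slice(i, None, 2),
                          slice(j, None, 2), slice(l, None, 2))
                    slices[(i, j, l)] = sl
                    out[sl] = np.matmul(w.data[:, :, i, j, l], xin).reshape(
                        N, self.c_out, sx, sy, sz
                    )
        out += b.data[None, :, None, None, None]

        def backward(g):
            if b.requires_grad:
                b.accumulate_grad(g.sum(axis=(0, 2, 3, 4)))
            if w.requires_grad:
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
            if x.requires_grad:
                dx = np.zeros((N, C, V), dtype=np.float32)
            for (i, j, l), sl in slices.items():
                gt = np.ascontiguousarray(g[sl]).reshape(N, self.c_out, V)
                if w.requires_grad:
                    w.grad[:, :, i, j, l] += np.einsum(
                        "nov,ncv->oc", gt, xin, optimize=True
                    )
                if x.requires_grad:
                    dx += np.matmul(w.data[:, :, i, j, l].T, gt)
            if x.requires_grad:
                x.accumulate_grad(dx.reshape(N, C, sx, sy, sz))

        return Tensor(out, parents=(x, w, b), backward=backward)


class BatchNorm3d(Module):
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    @property
    def running_mean(self):
        return self._buffers["running_mean"]

    @property
    def running_var(self):
        return self._buffers["running_var"]

    def forward(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        axes = (0, 2, 3, 4)
        cshape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            m = float(x.data.size // x.data.shape[1])
            self._buffers["running_mean"] += self.momentum * (mu - self._buffers["running_mean"])
            self._buffers["running_var"] += self.momentum * (
                var * m / max(m - 1.0, 1.0) - self._buffers["running_var"]
            )
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x.data - mu.reshape(cshape)) * ivar.reshape(cshape)
            out = g.data.reshape(cshape) * xhat + b.data.reshape(cshape)

            def backward(grad):
                if g.requires_grad:
                    g.accumulate_grad((grad * xhat).sum(axis=axes))
                if b.requires_grad:
                    b.accumulate_grad(grad.sum(axis=axes))
                if x.requires_grad:
                    dxhat = grad * g.data.reshape(cshape)
                    s1 = dxhat.sum(axis=axes).reshape(cshape)
                    s2 = (dxhat * xhat).sum(axis=axes).reshape(cshape)
                    dx = (dxhat - s1 / m - xhat * s2 / m) * ivar.reshape(cshape)
                    x.accumulate_grad(dx.astype(np.float32))

            return Tensor(out, parents=(x, g, b), backward=backward)

        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (g.data * ivar).reshape(cshape)
        shift = (b.data - g.data * self.running_mean * ivar).reshape(cshape)
        out = x.data * scale + shift

        def backward(grad):
            if g.requires_grad:
                xhat = (x.data - self.running_mean.reshape(cshape)) * ivar.reshape(cshape)
                g.accumulate_grad((grad * xhat).sum(axis=axes))
            if b.requires_grad:
                b.accumulate_grad(grad.sum(axis=axes))
            if x.requires_grad:
                x.accumulate_grad(grad * scale)

        return Tensor(out, parents=(x, g, b), backward=backward)


class PReLU(Module):
    """Parametric ReLU with one learnable negative slope per channel."""

    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.alpha = Parameter(np.full(channels, init, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        a = self.alpha
        cshape = (1, -1) + (1,) * (x.data.ndim - 2)
        neg = x.data < 0
        out = np.where(neg, x.data * a.data.reshape(cshape), x.data)

        def backward(g):
            if a.requires_grad:
                a.accumulate_grad((g * np.where(neg, x.data, 0.0)).sum(
                    axis=(0,) + tuple(range(2, x.data.ndim))
                ))
            if x.requires_grad:
                x.accumulate_grad(np.where(neg, g * a.data.reshape(cshape), g))

        return Tensor(out, parents=(x, a), backward=backward)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        pos = x.data > 0
        return _unary(x, np.where(pos, x.data, 0.0), lambda g: np.where(pos, g, 0.0))


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    Draws from the generator attached via :meth:`seed`, so a training run is
    reproducible from its configuration seed.
    """

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def seed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return _unary(x, x.data, lambda g: g)
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return _unary(x, x.data * mask, lambda g: g * mask)


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2 (even spatial dims required)."""

    def forward(self, x: Tensor) -> Tensor:
        N, C, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"max-pooling needs even spatial dims, got {(X, Y, Z)}")
        xb = x.data.reshape(N, C, X // 2, 2, Y // 2, 2, Z // 2, 2)
        xb = xb.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, X // 2, Y // 2, Z // 2, 8)
        idx = xb.argmax(axis=-1)
        out = np.take_along_axis(xb, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if x.requires_grad:
                buf = np.zeros_like(xb)
                np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
                buf = buf.reshape(N, C, X // 2, Y // 2, Z // 2, 2, 2, 2)
                buf = buf.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, X, Y, Z)
                x.accumulate_grad(buf)

        return Tensor(out, parents=(x,), backward=backward)


class Upsample3d(Module):
    """Nearest-neighbour 2x upsampling (no parameters)."""

    def forward(self, x: Tensor) -> Tensor:
        N, C, X, Y, Z = x.shape
        out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)

        def backward(g):
            if x.requires_grad:
                gb = g.reshape(N, C, X, 2, Y, 2, Z, 2)
                x.accumulate_grad(gb.sum(axis=(3, 5, 7)))

        return Tensor(out, parents=(x,), backward=backward)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def count_parameters(module: Module) -> int:
    """Exact number of trainable scalars in a module tree."""
    return int(sum(p.data.size for p in module.parameters()))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class NesterovAdam:
    """Nesterov-accelerated Adam (Nadam).

    Adam's first-moment estimate with the Nesterov look-ahead applied to the
    update, following the published algorithm without the momentum-decay
    schedule:

        m_t = b1 m_{t-1} + (1-b1) g_t
        v_t = b2 v_{t-1} + (1-b2) g_t^2
        update = [b1 m_t/(1-b1^{t+1}) + (1-b1) g_t/(1-b1^t)] / (sqrt(v_t/(1-b2^t)) + eps)
    """

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        t, b1, b2 = self.t, self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            m_hat = m / (1.0 - b1 ** (t + 1))
            v_hat = v / (1.0 - b2 ** t)
            update = (b1 * m_hat + (1.0 - b1) * g / (1.0 - b1 ** t)) / (
                np.sqrt(v_hat) + self.eps
            )
            p.data -= (lr * update).astype(p.data.dtype)
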