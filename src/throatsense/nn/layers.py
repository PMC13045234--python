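"""Neural-network layers on the autograd engine.

Hand-written forward/backward for the structured ops (convolution via
9-slice im2col, pooling, batch/layer norm); everything recurrent and
attentional is composed from autograd primitives.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, softmax

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "MaxPool2d",
    "BatchNorm2d",
    "LayerNorm",
    "Dropout",
    "LSTM",
    "MultiHeadSelfAttention",
    "TransformerEncoderBlock",
]


def _narrow(t: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis with allocation-free gradient add."""
    sl = [slice(None)] * t.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        if t.requires_grad:
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
            t.grad[sl] += g

    return Tensor._make(t.data[sl], (t,), backward)


def _stack_time(tensors, axis: int = 1) -> Tensor:
    """Stack (B, H) tensors into (B, T, H) along a new time axis."""
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, k, axis=axis))

    return Tensor._make(data, tuple(tensors), backward)


class Module:
    """Minimal container: tracks parameters and train/eval mode."""

    def __init__(self):
        self._params: list = []
        self._children: list = []
        self.training = True

    def add_param(self, array) -> Tensor:
        p = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)
        self._params.append(p)
        return p

    def add_module(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self):
        out = list(self._params)
        for child in self._children:
            out.extend(child.parameters())
        return out

    def train(self):
        self.training = True
        for c in self._children:
            c.train()
        return self

    def eval(self):
        self.training = False
        for c in self._children:
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        """All learnable and buffer arrays, for checkpointing."""
        arrays = [p.data for p in self._params]
        for c in self._children:
            arrays.extend(c.state_arrays())
        return arrays

    def load_arrays(self, arrays):
        flat = self.state_arrays()
        if len(arrays) != len(flat):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model needs {len(flat)}")
        for dst, src in zip(flat, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = self.add_param(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = self.add_param(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3x3 same-padding convolution, stride 1, via slice-wise im2col."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = self.add_param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, fan_in))
        )
        self.bias = self.add_param(np.zeros(out_channels))

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        b, c = xp.shape[0], xp.shape[1]
        k = self.kernel_size
        cols = np.empty((b, c * k * k, h * w), dtype=xp.dtype)
        n = 0
        for i in range(k):
            for j in range(k):
                patch = xp[:, :, i : i + h, j : j + w].reshape(b, c, h * w)
                cols[:, n * c : (n + 1) * c, :] = patch
                n += 1
        return cols

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = self._im2col(xp, h, w)
        # weight stored (O, C*k*k) but im2col orders patches (offset, channel);
        # rearrange weight to match: (O, k*k, C) -> (O, k*k*C)
        wr = (
            self.weight.data.reshape(self.out_channels, self.in_channels, k * k)
            .transpose(0, 2, 1)
            .reshape(self.out_channels, -1)
        )
        y = np.matmul(wr, cols).reshape(b, self.out_channels, h, w)
        y += self.bias.data[None, :, None, None]
        weight, bias = self.weight, self.bias

        def backward(g):
            gr = g.reshape(b, self.out_channels, h * w)
            if weight.requires_grad:
                dwr = np.einsum("boi,bci->oc", gr, cols, optimize=True)
                dw = (
                    dwr.reshape(self.out_channels, k * k, self.in_channels)
                    .transpose(0, 2, 1)
                    .reshape(self.out_channels, -1)
                )
                weight._accum(dw)
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dcols = np.matmul(wr.T, gr)  # (b, c*k*k, h*w)
                dxp = np.zeros_like(xp)
                n = 0
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i : i + h, j : j + w] += dcols[
                            :, n * c : (n + 1) * c, :
                        ].reshape(b, c, h, w)
                        n += 1
                x._accum(dxp[:, :, pad : pad + h, pad : pad + w])

        return Tensor._make(y, (x, weight, bias), backward)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; input height/width must be even."""

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(h, w)}")
        subs = [
            x.data[:, :, i::2, j::2] for i in (0, 1) for j in (0, 1)
        ]  # strided views, no copies
        y = np.maximum(np.maximum(subs[0], subs[1]), np.maximum(subs[2], subs[3]))

        def backward(g):
            if x.requires_grad:
                dx = np.zeros_like(x.data)
                taken = np.zeros(y.shape, dtype=bool)
                for (i, j), sub in zip(((0, 0), (0, 1), (1, 0), (1, 1)), subs):
                    hit = (sub == y) & ~taken  # first-match wins on ties
                    dx[:, :, i::2, j::2] = np.where(hit, g, 0.0)
                    taken |= hit
                x._accum(dx)

        return Tensor._make(y, (x,), backward)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = self.add_param(np.ones(channels))
        self.beta = self.add_param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def state_arrays(self):
        return super().state_arrays() + [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        gamma, beta = self.gamma, self.beta
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
                if not training:
                    x._accum(g * gi)
                    return
                n = g.shape[0] * g.shape[2] * g.shape[3]
                dxhat = g * gamma.data[None, :, None, None]
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dx = (dxhat - s1 / n - xhat * s2 / n) * inv_std[None, :, None, None]
                x._accum(dx)

        return Tensor._make(y, (x, gamma, beta), backward)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(np.ones(dim))
        self.beta = self.add_param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_std
        y = self.gamma.data * xhat + self.beta.data
        gamma, beta = self.gamma, self.beta

        def backward(g):
            if gamma.requires_grad:
                red = tuple(range(g.ndim - 1))
                gamma._accum((g * xhat).sum(axis=red))
                beta._accum(g.sum(axis=red))
            if x.requires_grad:
                n = g.shape[-1]
                dxhat = g * gamma.data
                s1 = dxhat.sum(axis=-1, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=-1, keepdims=True)
                x._accum((dxhat - s1 / n - xhat * s2 / n) * inv_std)

        return Tensor._make(y, (x, gamma, beta), backward)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0 or rng is None:
            return x
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(mask)


class LSTM(Module):
    """Multi-layer (optionally bidirectional) LSTM over (B, T, I) input."""

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator, bidirectional: bool = True,
                 dropout: float = 0.0):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.dirs = 2 if bidirectional else 1
        self.dropout = self.add_module(Dropout(dropout))
        self.cells = []
        for layer in range(num_layers):
            in_dim = input_size if layer == 0 else hidden_size * self.dirs
            per_dir = []
            for _ in range(self.dirs):
                scale = 1.0 / np.sqrt(hidden_size)
                wx = self.add_param(rng.uniform(-scale, scale, (in_dim, 4 * hidden_size)))
                # orthogonal recurrent blocks condition the recurrence well
                wh_blocks = []
                for _gate in range(4):
                    q, _ = np.linalg.qr(rng.standard_normal((hidden_size, hidden_size)))
                    wh_blocks.append(q)
                wh = self.add_param(np.concatenate(wh_blocks, axis=1))
                b = np.zeros(4 * hidden_size)
                b[hidden_size : 2 * hidden_size] = 1.0  # forget-gate bias
                per_dir.append((wx, wh, self.add_param(b)))
            self.cells.append(per_dir)

    def _run_direction(self, x: Tensor, params, reverse: bool) -> Tensor:
        wx, wh, b = params
        bsz, t_len = x.shape[0], x.shape[1]
        hs = self.hidden_size
        # input contribution for all timesteps in one large GEMM
        xw = (x.reshape(bsz * t_len, -1) @ wx + b).reshape(bsz, t_len, 4 * hs)
        h = Tensor(np.zeros((bsz, hs), dtype=np.float32))
        c = Tensor(np.zeros((bsz, hs), dtype=np.float32))
        order = range(t_len - 1, -1, -1) if reverse else range(t_len)
        outs = [None] * t_len
        for t in order:
            gates = _narrow(xw, 1, t, 1).reshape(bsz, -1) + h @ wh
            i = _narrow(gates, 1, 0, hs).sigmoid()
            f = _narrow(gates, 1, hs, hs).sigmoid()
            g = _narrow(gates, 1, 2 * hs, hs).tanh()
            o = _narrow(gates, 1, 3 * hs, hs).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        return _stack_time(outs, axis=1)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        out = x
        for layer, per_dir in enumerate(self.cells):
            seqs = [
                self._run_direction(out, per_dir[d], reverse=bool(d))
                for d in range(self.dirs)
            ]
            out = seqs[0] if len(seqs) == 1 else concat(seqs, axis=2)
            if layer < self.num_layers - 1:
                out = self.dropout(out, rng)
        return out


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        scale = np.sqrt(1.0 / d_model)
        self.wq = self.add_param(rng.normal(0.0, scale, (d_model, d_model)))
        self.wk = self.add_param(rng.normal(0.0, scale, (d_model, d_model)))
        self.wv = self.add_param(rng.normal(0.0, scale, (d_model, d_model)))
        self.wo = self.add_param(rng.normal(0.0, scale, (d_model, d_model)))
        self.bo = self.add_param(np.zeros(d_model))

    def _heads(self, x: Tensor, w: Tensor, b: int, t: int) -> Tensor:
        return (x @ w).reshape(b, t, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        q = self._heads(x, self.wq, b, t)
        k = self._heads(x, self.wk, b, t)
        v = self._heads(x, self.wv, b, t)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, t, self.d_model)
        return ctx @ self.wo + self.bo


class TransformerEncoderBlock(Module):
    """One pre-built encoder block: MHA + residual/LN, FFN + residual/LN."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.attn = self.add_module(MultiHeadSelfAttention(d_model, n_heads, rng))
        self.ln1 = self.add_module(LayerNorm(d_model))
        self.ff1 = self.add_module(Linear(d_model, d_ff, rng))
        self.ff2 = self.add_module(Linear(d_ff, d_model, rng))
        self.ln2 = self.add_module(LayerNorm(d_model))

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.attn(x))
        x = self.ln2(x + self.ff2(self.ff1(x).relu()))
        return x
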