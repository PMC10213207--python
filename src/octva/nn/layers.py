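"""Neural-network building blocks on the autodiff engine.

Contains the pieces the fusion model is assembled from: linear and
convolutional layers, layer normalization, multi-headed self-attention
with the scaled-dot-product form softmax(Q K^T / sqrt(d_k)) V, the
transformer encoder layer (MSA + residual + LN, FFN + residual + LN),
and a compact residual convolutional backbone that flattens each B-scan
into a 512-dim feature vector.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, conv2d

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "ConvBackbone",
]


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale=None):
        if scale is None:
            scale = np.sqrt(2.0 / (n_in + n_out))  # Glorot
        self.w = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, stride, padding, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He
        self.w = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, k, k)), requires_grad=True
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention, split over ``n_heads`` heads."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.n_heads = d_model, n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, length, _ = x.shape

        def _heads(t: Tensor) -> Tensor:
            return t.reshape(n, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = _heads(self.wq(x)), _heads(self.wk(x)), _heads(self.wv(x))
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        att = att.softmax(axis=-1)
        out = att @ v  # (n, heads, L, d_head)
        out = out.transpose(0, 2, 1, 3).reshape(n, length, self.d_model)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """MSA and FFN blocks, each with a residual connection and LayerNorm."""

    def __init__(self, d_model: int, n_heads: int, d_ffn: int, rng: np.random.Generator):
        self.msa = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.fc1 = Linear(d_model, d_ffn, rng)
        self.fc2 = Linear(d_ffn, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.msa(x))
        return self.ln2(x + self.fc2(self.fc1(x).relu()))


class _ResBlock(Module):
    """conv-relu-conv with a strided 1x1 projection skip, no normalization."""

    def __init__(self, c_in, c_out, stride, rng):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.proj = Conv2d(c_in, c_out, 1, stride, 0, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        return (h + self.proj(x)).relu()


class ConvBackbone(Module):
    """Residual CNN feature extractor for one grayscale B-scan.

    A strided stem and three residual stages downsample the frame 16x;
    global average pooling and a linear layer flatten the result into a
    512-dim feature vector, the width the downstream token encoder
    expects from an image branch.
    """

    FEATURE_DIM = 512

    def __init__(self, rng: np.random.Generator, channels=(8, 16, 32, 64)):
        c0, c1, c2, c3 = channels
        self.stem = Conv2d(1, c0, 3, 2, 1, rng)
        self.block1 = _ResBlock(c0, c1, 2, rng)
        self.block2 = _ResBlock(c1, c2, 2, rng)
        self.block3 = _ResBlock(c2, c3, 2, rng)
        self.fc = Linear(c3, self.FEATURE_DIM, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("backbone expects (N, 1, H, W) input")
        h = self.stem(x).relu()
        h = self.block3(self.block2(self.block1(h)))
        pooled = h.mean(axis=(2, 3))  # (N, C)
        return self.fc(pooled).relu()
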