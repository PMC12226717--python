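"""Neural building blocks on the numpy autodiff engine.

Includes the attention units the fusion networks are built from: the
squeeze-and-excitation (SE) channel gate, the SE-residual "Se-Conv"
block, the convolutional block attention module (CBAM, channel then
spatial attention applied sequentially), multi-head scaled dot-product
attention over modality tokens, and a post-norm transformer encoder
layer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Sequential", "Linear", "Conv2d", "BatchNorm2d", "MaxPool2d",
    "ReLU", "SEBlock", "SEConvBlock", "CBAM", "CBAMResidualBlock",
    "MultiheadAttention", "TransformerEncoderLayer", "LayerNorm", "MLP",
]


class Module:
    """Minimal module base: parameter registry, train/eval mode, counting."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield (f"{prefix}{n}", p)
        for n, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{n}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.relu()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x):
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        super().__init__()
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                        (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Training batches update the running mean/var (momentum 0.1);
    evaluation uses the running statistics only.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :, None, None])
            var = Tensor(self.running_var[None, :, None, None])
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x):
        return x.maxpool2d(self.kernel, self.stride)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Global-average-pool -> FC(C -> C/r) -> ReLU -> FC(-> C) -> sigmoid,
    then per-channel multiplicative scaling of the input map.  Gates lie
    strictly inside (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if reduction > channels:
            raise ValueError(f"reduction {reduction} exceeds channels {channels}")
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.last_gates: np.ndarray | None = None

    def forward(self, x):
        pooled = x.mean(axis=(2, 3))                      # (N, C)
        s = self.fc2(self.fc1(pooled).relu()).sigmoid()   # (N, C)
        self.last_gates = s.data
        N, C = s.shape
        return x * s.reshape(N, C, 1, 1)


class SEConvBlock(Module):
    """Residual conv block with an SE gate on the residual path ("Se-Conv").

    out = shortcut(F) + SE(conv-bn-relu-conv-bn(F)); with zero conv
    weights and matching widths the block is a pure pass-through.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, reduction: int = 8):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm2d(c_out)
        self.se = SEBlock(c_out, min(reduction, c_out), rng)
        if c_in != c_out or stride != 1:
            self.proj = Conv2d(c_in, c_out, 1, rng, stride=stride)
        else:
            self.proj = None

    def forward(self, x):
        path = self.bn1(self.conv1(x)).relu()
        path = self.bn2(self.conv2(path))
        path = self.se(path)
        shortcut = x if self.proj is None else self.proj(x)
        return shortcut + path


class CBAM(Module):
    """Convolutional block attention: channel gate, then spatial gate.

    F' = M_channel(F) * F (shared two-layer bottleneck over the average-
    and max-pooled channel descriptors, sigmoid); F'' = M_spatial(F') *
    F' (conv over the channel-pooled 2-plane stack, sigmoid).  Both
    attention maps are returned alongside F''.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 8, spatial_kernel: int = 7):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, rng,
                                   padding=spatial_kernel // 2)
        self.last_channel_map: np.ndarray | None = None
        self.last_spatial_map: np.ndarray | None = None

    def forward(self, x):
        N, C = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        mc = (self.fc2(self.fc1(avg).relu())
              + self.fc2(self.fc1(mx).relu())).sigmoid()   # (N, C)
        f1 = x * mc.reshape(N, C, 1, 1)
        savg = f1.mean(axis=1, keepdims=True)
        smax = f1.max(axis=1, keepdims=True)
        ms = self.spatial_conv(concat([savg, smax], axis=1)).sigmoid()  # (N,1,H,W)
        out = f1 * ms
        self.last_channel_map = mc.data
        self.last_spatial_map = ms.data[:, 0]
        return out, mc, ms


class CBAMResidualBlock(Module):
    """Residual block with CBAM applied to the residual path."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, reduction: int = 8, use_cbam: bool = True,
                 spatial_kernel: int = 7):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm2d(c_out)
        self.cbam = CBAM(c_out, rng, reduction=min(reduction, c_out),
                         spatial_kernel=spatial_kernel) if use_cbam else None
        if c_in != c_out or stride != 1:
            self.proj = Conv2d(c_in, c_out, 1, rng, stride=stride)
        else:
            self.proj = None

    def forward(self, x):
        path = self.bn1(self.conv1(x)).relu()
        path = self.bn2(self.conv2(path))
        if self.cbam is not None:
            path, _, _ = self.cbam(path)
        shortcut = x if self.proj is None else self.proj(x)
        return (shortcut + path).relu()


class MultiheadAttention(Module):
    """Scaled dot-product attention over modality tokens (N, M, D)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_weights: np.ndarray | None = None

    def forward(self, tokens):
        N, M, D = tokens.shape
        if M == 0:
            raise ValueError("attention needs at least one token")
        h, dh = self.n_heads, self.d_head

        def split(t):  # (N,M,D) -> (N,h,M,dh)
            return t.reshape(N, M, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(tokens)), split(self.wk(tokens)), split(self.wv(tokens))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)                     # rows sum to 1
        self.last_weights = attn.data
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(N, M, D)
        return self.wo(out), attn


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention + FFN, each with residual + LN."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_ff: int = None):
        super().__init__()
        d_ff = d_ff or 2 * d_model
        self.attn = MultiheadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def forward(self, tokens):
        a, _ = self.attn(tokens)
        x = self.ln1(tokens + a)
        f = self.ff2(self.ff1(x).relu())
        return self.ln2(x + f)


class MLP(Module):
    def __init__(self, sizes: list[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def forward(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x
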