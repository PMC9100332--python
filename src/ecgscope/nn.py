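"""Neural-network layers and the Adam optimizer used by the ECG model.

Layers follow the standard contracts: batch normalization keeps running
statistics for inference, dropout is active only in training mode, the
transformer encoder layer is the post-norm original (self-attention ->
add & norm -> feed-forward -> add & norm) with dropout applied to each
sub-layer output.  Parameter initialization is uniform fan-in
(U(-1/sqrt(fan_in), 1/sqrt(fan_in))) from a caller-supplied generator so
whole-model construction is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, layer_norm

__all__ = [
    "Module", "Linear", "Conv1d", "MaxPool1d", "LayerNorm", "BatchNorm1d",
    "Dropout", "MultiHeadAttention", "TransformerEncoderLayer",
    "TransformerEncoder", "Sequential", "ReLU", "Adam",
]


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    """Minimal module base: parameter registry + train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k in getattr(self, "_buffer_names", ()):
            out[prefix + k] = getattr(self, k)
        for name, child in self._children.items():
            out.update(child.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({"buffer:" + k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        bufs = self._buffer_owners()
        for key, value in state.items():
            if key.startswith("buffer:"):
                owner, attr = bufs[key[len("buffer:"):]]
                setattr(owner, attr, np.asarray(value).copy())
            else:
                params[key].data = np.asarray(value).copy()

    def _buffer_owners(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        out = {}
        for k in getattr(self, "_buffer_names", ()):
            out[prefix + k] = (self, k)
        for name, child in self._children.items():
            out.update(child._buffer_owners(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Tensor(_uniform_fan_in(rng, in_features,
                                             (in_features, out_features), dtype),
                             requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, in_features,
                                           (out_features,), dtype),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            # one large GEMM instead of many small batched ones
            lead = x.shape[:-1]
            flat = x.reshape(-1, x.shape[-1])
            return (flat @ self.weight + self.bias).reshape(
                *lead, self.weight.shape[1])
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Single-input-channel 'valid' 1-D convolution via im2col.

    Input (B, L) -> output (B, L - kernel + 1, filters); stride 1.
    """

    def __init__(self, filters: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.kernel = kernel
        self.weight = Tensor(_uniform_fan_in(rng, kernel, (kernel, filters), dtype),
                             requires_grad=True)
        self.bias = Tensor(_uniform_fan_in(rng, kernel, (filters,), dtype),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, length = x.shape
        k = self.kernel
        n = length - k + 1
        if n < 1:
            raise ValueError(f"input length {length} shorter than kernel {k}")
        idx = np.arange(n)[:, None] + np.arange(k)[None, :]
        patches = x[:, idx]            # (B, n, k) with gradient routing
        return patches @ self.weight + self.bias


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def __call__(self, x: Tensor) -> Tensor:
        return x.maxpool1d(self.kernel, self.stride)


class ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class BatchNorm1d(Module):
    """Batch normalization over the leading (batch) axis of (B, C) inputs.

    Training mode normalizes with per-batch statistics and updates running
    estimates; evaluation mode uses the running estimates.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=dtype)
        self.running_var = np.ones(dim, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1))
            inv = (var + self.eps) ** -0.5
            return xc * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * inv * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Linear(d_model, d_model, rng, dtype)
        self.wk = Linear(d_model, d_model, rng, dtype)
        self.wv = Linear(d_model, d_model, rng, dtype)
        self.wo = Linear(d_model, d_model, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, dh = self.heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, n, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * float(1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.wo(ctx)


class TransformerEncoderLayer(Module):
    def __init__(self, d_model: int, heads: int, d_ff: int, dropout_p: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, heads, rng, dtype)
        self.ff1 = Linear(d_model, d_ff, rng, dtype)
        self.ff2 = Linear(d_ff, d_model, rng, dtype)
        self.norm1 = LayerNorm(d_model, dtype)
        self.norm2 = LayerNorm(d_model, dtype)
        self.drop1 = Dropout(dropout_p, rng)
        self.drop2 = Dropout(dropout_p, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ff2(self.ff1(x).relu())))
        return x


class TransformerEncoder(Module):
    def __init__(self, layers: int, d_model: int, heads: int, d_ff: int,
                 dropout_p: float, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.layers = [TransformerEncoderLayer(d_model, heads, d_ff,
                                               dropout_p, rng, dtype)
                       for _ in range(layers)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def __call__(self, x: Tensor) -> Tensor:
        for step in self.steps:
            x = step(x)
        return x


class Adam:
    """Adam optimizer (bias-corrected first/second moment estimates)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.98, eps: float = 1e-9):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
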