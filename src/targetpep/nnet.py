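"""Neural-network building blocks on the in-package autodiff core.

Layers follow the conventional shapes: activations are ``(batch, length,
channels)`` tensors, linear layers act on the last axis, attention runs over
the length axis with an optional validity mask for padded positions.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Linear",
    "LoRALinear",
    "Adapter",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "FeedForward",
    "TransformerLayer",
    "Conv1d",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state dicts."""

    def __init__(self):
        self.training = True

    # attribute order is insertion order, which makes traversal deterministic
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def children(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value

    def train(self, mode: bool = True):
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={missing}, extra={extra}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True

    def num_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.data.size
            for p in self.parameters()
            if p.requires_grad or not trainable_only
        )


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        for i, m in enumerate(modules):
            setattr(self, str(i), m)

    def __iter__(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield value

    def __getitem__(self, i):
        items = list(self)
        return items[i]

    def __len__(self):
        return sum(1 for _ in self)

    def append(self, m: Module):
        setattr(self, str(len(self)), m)


def _init_weight(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    scale = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-scale, scale, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.weight = Parameter(np.zeros((d_in, d_out)))
        else:
            self.weight = Parameter(_init_weight(rng, d_in, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    __call__ = forward


class LoRALinear(Module):
    """A frozen linear map plus a trainable low-rank update.

    The forward pass is ``h = x W0 + x A^T B^T`` with ``A (r, d_in)`` drawn
    from a small Gaussian and ``B (d_out, r)`` initialised to zero, so the
    wrapped layer starts bit-identical to the frozen base layer.
    """

    def __init__(self, base: Linear, r: int, rng: np.random.Generator):
        super().__init__()
        d_in, d_out = base.weight.data.shape
        if r >= min(d_in, d_out):
            import warnings

            warnings.warn(
                f"LoRA rank {r} is not small relative to ({d_in},{d_out})",
                stacklevel=2,
            )
        self.base = base
        self.base.freeze()
        self.lora_A = Parameter(rng.normal(0.0, 0.01, size=(r, d_in)))
        self.lora_B = Parameter(np.zeros((d_out, r)))

    def forward(self, x: Tensor) -> Tensor:
        at = self.lora_A.transpose(1, 0)
        bt = self.lora_B.transpose(1, 0)
        return self.base(x) + (x @ at) @ bt

    __call__ = forward


class Adapter(Module):
    """Bottleneck adapter with a skip connection.

    The up-projection is zero-initialised, so a freshly inserted adapter is
    exactly the identity map.
    """

    def __init__(self, d_model: int, bottleneck: int, rng: np.random.Generator):
        super().__init__()
        self.down = Linear(d_model, bottleneck, rng)
        self.up = Linear(bottleneck, d_model, rng, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return x + self.up(self.down(x).gelu())

    __call__ = forward


class Embedding(Module):
    def __init__(self, n_vocab: int, d_model: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_vocab, d_model)))

    def forward(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(indices))

    __call__ = forward


class LayerNorm(Module):
    def __init__(self, d_model: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d_model))
        self.beta = Parameter(np.zeros(d_model))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred ** 2).mean(axis=-1, keepdims=True)
        return centred / ((var + self.eps) ** 0.5) * self.gamma + self.beta

    __call__ = forward


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep

    __call__ = forward


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q_proj = Linear(d_model, d_model, rng)
        self.k_proj = Linear(d_model, d_model, rng)
        self.v_proj = Linear(d_model, d_model, rng)
        self.out_proj = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q = split(self.q_proj(x))
        k = split(self.k_proj(x))
        v = split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        if mask is not None:
            bias = np.where(np.asarray(mask, bool), 0.0, -1e9)[:, None, None, :]
            scores = scores + bias
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.out_proj(out)

    __call__ = forward


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    __call__ = forward


class TransformerLayer(Module):
    """Pre-norm transformer encoder layer with optional adapter slots."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.adapter_attn: Adapter | None = None
        self.adapter_ffn: Adapter | None = None

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        a = self.attn(self.ln1(x), mask)
        if self.adapter_attn is not None:
            a = self.adapter_attn(a)
        x = x + a
        f = self.ffn(self.ln2(x))
        if self.adapter_ffn is not None:
            f = self.adapter_ffn(f)
        return x + f

    __call__ = forward


class Conv1d(Module):
    """Same-padded 1-D convolution over the length axis of (B, L, C) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        if zero_init:
            self.weight = Parameter(np.zeros((kernel, c_in, c_out)))
        else:
            self.weight = Parameter(_init_weight(rng, c_in * kernel,
                                                 (kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        half = self.kernel // 2
        zeros = Tensor(np.zeros((B, half, C)))
        xp = concat([zeros, x, zeros], axis=1)
        u = xp.unfold1d(self.kernel)  # (B, L, k*C)
        w = self.weight.reshape(self.kernel * C, -1)
        return u @ w + self.bias

    __call__ = forward


class Adam:
    """Adam optimiser; parameters with ``requires_grad=False`` are skipped,
    which is how head/backbone freezing is enforced during training."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = {id(p): np.zeros_like(p.data) for p in self.params}
        self._v = {id(p): np.zeros_like(p.data) for p in self.params}
        self._t = {id(p): 0 for p in self.params}

    def step(self):
        for p in self.params:
            if not p.requires_grad or p.grad is None:
                continue
            k = id(p)
            self._t[k] += 1
            t = self._t[k]
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * p.grad
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self._m[k] / (1 - self.b1 ** t)
            vhat = self._v[k] / (1 - self.b2 ** t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
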