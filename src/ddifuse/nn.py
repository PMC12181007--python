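"""Neural-network building blocks: modules, layers and the Adam optimizer.

Parameter initialisation is driven by an explicit ``numpy.random.Generator``
so that a model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from ._tensor import DTYPE, Tensor, concat, masked_softmax
from .errors import DimensionMismatch


class Module:
    """Base class with recursive parameter discovery and train/eval state."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((prefix + name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix + name + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{prefix}{name}.{i}", item))
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for val in vars(self).values():
            if isinstance(val, Module):
                val.train(mode)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise DimensionMismatch(f"state dict keys mismatch: {sorted(missing)}")
        for name, arr in state.items():
            if own[name].data.shape != arr.shape:
                raise DimensionMismatch(
                    f"{name}: expected {own[name].data.shape}, got {arr.shape}"
                )
            own[name].data = arr.astype(DTYPE).copy()


def _param(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:  # Glorot-uniform for weight matrices
        fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
        scale = float(np.sqrt(6.0 / (fan_in + fan_out)))
        return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (d_in, d_out))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        d_in, d_out = self.weight.shape
        if x.shape[-1] != d_in:
            raise DimensionMismatch(
                f"Linear expects last dim {d_in}, got {x.shape[-1]}"
            )
        lead = x.shape[:-1]
        flat = x.reshape(-1, d_in) if x.ndim != 2 else x  # one big GEMM
        out = flat @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(*lead, d_out) if x.ndim != 2 else out


class Embedding(Module):
    """Lookup table; row 0 can be reserved for PAD (zero-initialised)."""

    def __init__(self, rng: np.random.Generator, n: int, d: int, scale: float = 0.02):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, scale, size=(n, d)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.take_rows(idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * Tensor(keep)


class FeedForward(Module):
    def __init__(self, rng, d: int, d_hidden: int, dropout: Dropout | None = None):
        super().__init__()
        self.fc1 = Linear(rng, d, d_hidden)
        self.fc2 = Linear(rng, d_hidden, d)
        self.dropout = dropout

    def __call__(self, x: Tensor) -> Tensor:
        h = self.fc1(x).relu()
        if self.dropout is not None:
            h = self.dropout(h)
        return self.fc2(h)


class MultiHeadAttention(Module):
    """Scaled-dot-product attention with optional additive per-head bias and
    an optional ProbSparse query budget.

    ``bias`` has shape (B, H, n, n) and is added to the attention logits.
    When ``top_u`` is given, only the ``top_u`` queries with the largest
    sparsity measurement (max minus mean of their logit row) receive exact
    attention; the remaining queries fall back to the masked mean of the
    value vectors, as in ProbSparse self-attention.
    """

    def __init__(self, rng, d_model: int, n_heads: int):
        super().__init__()
        if d_model % n_heads:
            raise DimensionMismatch(f"d_model {d_model} not divisible by {n_heads} heads")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)

    def _split(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        return x.reshape(b, n, self.h, self.dk).transpose(0, 2, 1, 3)

    def __call__(
        self,
        x: Tensor,
        mask: np.ndarray,
        bias: Tensor | None = None,
        top_u: int | np.ndarray | None = None,
    ) -> Tensor:
        b, n, d = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        logits = q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(self.dk))
        if bias is not None:
            logits = logits + bias
        key_mask = np.asarray(mask, dtype=bool).reshape(b, 1, 1, n)
        attn = masked_softmax(logits, key_mask, axis=-1)
        out = attn @ v  # (B, H, n, dk)

        if top_u is not None:
            u = np.broadcast_to(np.asarray(top_u, dtype=np.int64), (b,))
            if np.any(u < n):
                # sparsity measurement on the raw logits (constants w.r.t. grad)
                n_keys = np.maximum(key_mask.sum(axis=-1), 1)
                row_sum = np.where(key_mask, logits.data, 0.0).sum(axis=-1)
                row_max = np.where(key_mask, logits.data, -np.inf).max(axis=-1)
                m = row_max - row_sum / n_keys
                m = np.where(np.asarray(mask, dtype=bool)[:, None, :], m, -np.inf)
                order = np.argsort(-m, axis=-1, kind="stable")
                rank = np.empty_like(order)
                np.put_along_axis(
                    rank, order, np.broadcast_to(np.arange(n), order.shape), axis=-1
                )
                sel = rank < u[:, None, None]
                counts = np.asarray(mask, dtype=DTYPE).sum(-1).reshape(b, 1, 1, 1)
                vmean = (v * Tensor(key_mask.astype(DTYPE).reshape(b, 1, n, 1))).sum(
                    axis=2, keepdims=True
                ) / Tensor(np.maximum(counts, 1.0))
                sel4 = sel[..., None]
                out = out * Tensor(sel4.astype(DTYPE)) + vmean * Tensor(1.0 - sel4)

        out = out.transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.wo(out)


class GRUCell(Module):
    """Standard three-gate GRU: z, r gates and candidate state n.

    h' = (1 - z) * n + z * h with n = tanh(Wn x + bn + r * (Un h + cn)).
    """

    def __init__(self, rng, d_in: int, d_hidden: int):
        super().__init__()
        self.wx = Linear(rng, d_in, 3 * d_hidden)
        self.wh = Linear(rng, d_hidden, 3 * d_hidden)
        self.d = d_hidden

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        if h.shape[-1] != self.d:
            raise DimensionMismatch(f"hidden dim {h.shape[-1]} != {self.d}")
        gx, gh = self.wx(x), self.wh(h)
        d = self.d
        z = (gx[..., 0:d] + gh[..., 0:d]).sigmoid()
        r = (gx[..., d : 2 * d] + gh[..., d : 2 * d]).sigmoid()
        nctx = (gx[..., 2 * d :] + r * gh[..., 2 * d :]).tanh()
        return (1.0 - z) * nctx + z * h


def masked_mean(x: Tensor, mask: np.ndarray, axis: int = 1) -> Tensor:
    """Mean of ``x`` over ``axis`` restricted to True positions of ``mask``."""
    m = np.asarray(mask, dtype=DTYPE)
    while m.ndim < x.ndim:
        m = m[..., None]
    counts = np.maximum(m.sum(axis=axis, keepdims=True), 1.0)
    return (x * Tensor(m)).sum(axis=axis, keepdims=False) / Tensor(
        np.take(counts, 0, axis=axis)
    )


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
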