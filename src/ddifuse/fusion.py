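"""Attention fusion of the per-drug view embeddings and the pair decoder.

Each enabled view embedding f (all projected to a common width) receives a
scalar logit w = W2 . tanh(W1 f + b) from a projection shared across views
and across both drugs; a softmax over the enabled views yields coefficients
(alpha_s, alpha_g, alpha_sem) that sum to one, and the fused drug embedding
is the corresponding convex combination.  A pair is scored by a three-layer
fully connected decoder on the concatenated fused embeddings, with a sigmoid
on the final scalar; training minimises binary cross-entropy.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat, stack
from .errors import DimensionMismatch, EmptyBatch
from .nn import Linear, Module

EPS_CLAMP = 1e-7


class AttentionFusion(Module):
    """Softmax attention over view embeddings (any non-empty subset of views)."""

    def __init__(self, rng: np.random.Generator, width: int = 75, d_att: int = 64):
        super().__init__()
        self.w1 = Linear(rng, width, d_att)   # W1 and b, shared across views
        self.w2 = Linear(rng, d_att, 1, bias=False)  # shared attention vector W2

    def __call__(self, views: list[Tensor]) -> tuple[Tensor, Tensor]:
        """``views``: list of (B, width) embeddings for the enabled channels.

        Returns (fused (B, width), coefficients (B, n_views)).
        """
        if not views:
            raise DimensionMismatch("fusion requires at least one view")
        widths = {v.shape[-1] for v in views}
        if len(widths) != 1:
            raise DimensionMismatch(f"view widths differ: {sorted(widths)}")
        logits = concat([self.w2(self.w1(v).tanh()) for v in views], axis=-1)
        shift = Tensor(logits.data.max(axis=-1, keepdims=True))
        z = (logits - shift).exp()
        alphas = z / z.sum(axis=-1, keepdims=True)
        stacked = stack(views, axis=1)                        # (B, V, width)
        fused = (stacked * alphas.reshape(*alphas.shape, 1)).sum(axis=1)
        return fused, alphas


class PairDecoder(Module):
    """Three fully connected layers with ReLU between, sigmoid output."""

    def __init__(
        self,
        rng: np.random.Generator,
        width: int = 75,
        hidden1: int = 256,
        hidden2: int = 64,
        symmetric: bool = False,
    ):
        super().__init__()
        self.symmetric = symmetric
        self.fc1 = Linear(rng, 2 * width, hidden1)
        self.fc2 = Linear(rng, hidden1, hidden2)
        self.fc3 = Linear(rng, hidden2, 1)

    def _logit(self, f_i: Tensor, f_j: Tensor) -> Tensor:
        x = concat([f_i, f_j], axis=-1)
        return self.fc3(self.fc2(self.fc1(x).relu()).relu())

    def __call__(self, f_i: Tensor, f_j: Tensor) -> Tensor:
        """Interaction probability for each pair; shape (B,)."""
        logit = self._logit(f_i, f_j)
        if self.symmetric:  # DDI labels are unordered; average both orders
            logit = (logit + self._logit(f_j, f_i)) * 0.5
        return logit.sigmoid().reshape(logit.shape[0])


def bce_loss(predictions: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, with predictions clamped away from {0, 1}."""
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise EmptyBatch("BCE over zero samples")
    p = predictions.clip(EPS_CLAMP, 1.0 - EPS_CLAMP)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()
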