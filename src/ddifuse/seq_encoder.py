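"""Transformer encoder for the SMILES-substructure sequence view.

Token-id sequences (PAD-padded to a fixed length ``k``) pass through learned
token and positional embeddings and a stack of pre-norm Transformer layers
with multi-head self-attention; the per-token states are mean-pooled over
non-PAD positions and projected to the sequence-view embedding ``f_seq``.

The default head count (8) does not divide the default output width (75),
so attention runs at an internal width of 80 (8 heads x 10) and a final
linear layer projects 80 -> 75.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor
from .errors import AllPadSequence
from .nn import (
    Dropout,
    Embedding,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    masked_mean,
)


class TransformerLayer(Module):
    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int, dropout: Dropout):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadAttention(rng, d_model, n_heads)
        self.ln2 = LayerNorm(d_model)
        self.ff = FeedForward(rng, d_model, d_ff, dropout)
        self.dropout = dropout

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = x + self.dropout(self.attn(self.ln1(x), mask))
        return x + self.dropout(self.ff(self.ln2(x)))


class SeqEncoder(Module):
    """Maps (B, k) token-id arrays to (B, d_out) sequence embeddings."""

    def __init__(
        self,
        rng: np.random.Generator,
        vocab_size: int,
        k: int = 50,
        d_model: int = 80,
        n_heads: int = 8,
        n_layers: int = 2,
        d_out: int = 75,
        dropout_p: float = 0.1,
    ):
        super().__init__()
        self.k = k
        self.tok_emb = Embedding(rng, vocab_size, d_model)
        self.tok_emb.weight.data[0] = 0.0  # PAD row
        self.pos_emb = Embedding(rng, k, d_model)
        drop = Dropout(dropout_p, rng)
        self.layers = [
            TransformerLayer(rng, d_model, n_heads, d_model, drop) for _ in range(n_layers)
        ]
        self.ln_final = LayerNorm(d_model)
        self.proj = Linear(rng, d_model, d_out)

    def __call__(self, token_ids: np.ndarray, lengths: np.ndarray) -> Tensor:
        """``token_ids``: (B, k) ints; ``lengths``: (B,) true lengths."""
        token_ids = np.asarray(token_ids)
        lengths = np.asarray(lengths)
        if np.any(lengths < 1):
            raise AllPadSequence("a sequence in the batch has true_length 0")
        # trailing all-PAD columns cannot affect the output (masking
        # contract), so drop them before running attention
        k_eff = int(lengths.max())
        if k_eff < token_ids.shape[1]:
            token_ids = token_ids[:, :k_eff]
        b, k = token_ids.shape
        mask = np.arange(k)[None, :] < lengths[:, None]
        x = self.tok_emb(token_ids) + self.pos_emb(np.broadcast_to(np.arange(k), (b, k)))
        # zero out PAD positions so positional embeddings cannot leak through
        x = x * Tensor(mask[..., None].astype(float))
        for layer in self.layers:
            x = layer(x, mask)
        x = self.ln_final(x)
        pooled = masked_mean(x, mask, axis=1)
        return self.proj(pooled)
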