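"""End-to-end drug-pair interaction model.

Both drugs of a pair go through the same shared-parameter encoders
(Siamese): the enabled view embeddings are fused per drug by softmax
attention, the two fused embeddings are concatenated and scored by the
three-layer decoder.  Featurisation (token ids, graph arrays, semantic
arrays) is static per drug and cached in a :class:`DrugFeaturizer`.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor
from .chem import DrugRecord, MolGraph, parse_drug
from .config import ModelConfig
from .fusion import AttentionFusion, PairDecoder
from .graph_encoder import GraphBatch, GraphEncoder, collate_graphs
from .nn import Module
from .semantic_encoder import (
    SemanticArrays,
    SemanticBatch,
    SemanticEncoder,
    collate_semantic,
    semantic_arrays,
)
from .seq_encoder import SeqEncoder
from .tokenizer import TokenSequence, Vocabulary, encode


class DrugFeaturizer:
    """Parses and featurises each drug once; lookups are cached by id."""

    def __init__(self, records: list[DrugRecord], vocab: Vocabulary, config: ModelConfig):
        self.vocab = vocab
        self.config = config
        self.graphs: dict[str, MolGraph] = {}
        self.tokens: dict[str, TokenSequence] = {}
        self.semantic: dict[str, SemanticArrays] = {}
        for rec in records:
            g = parse_drug(rec)
            self.graphs[rec.drug_id] = g
            self.tokens[rec.drug_id] = encode(rec.smiles, vocab, k=config.seq_k)
            self.semantic[rec.drug_id] = semantic_arrays(g)

    def collate_pairs(
        self, pairs: list[tuple[str, str]], labels: np.ndarray | None = None
    ) -> dict:
        """Build a batch over the unique drugs of ``pairs``."""
        unique = sorted({d for p in pairs for d in p})
        pos = {d: i for i, d in enumerate(unique)}
        batch: dict = {
            "idx1": np.array([pos[a] for a, _ in pairs]),
            "idx2": np.array([pos[b] for _, b in pairs]),
            "labels": None if labels is None else np.asarray(labels, dtype=float),
        }
        if "seq" in self.config.channels:
            toks = [self.tokens[d] for d in unique]
            batch["seq_ids"] = np.array([t.ids for t in toks], dtype=np.int64)
            batch["seq_len"] = np.array([t.true_length for t in toks], dtype=np.int64)
        if "graph" in self.config.channels:
            batch["graph"] = collate_graphs([self.graphs[d] for d in unique])
        if "semantic" in self.config.channels:
            batch["semantic"] = collate_semantic([self.semantic[d] for d in unique])
        return batch


class DDIModel(Module):
    def __init__(self, rng: np.random.Generator, config: ModelConfig, vocab_size: int):
        super().__init__()
        config.validate()
        self.config = config
        self.channels = tuple(config.channels)
        if "seq" in self.channels:
            self.seq_encoder = SeqEncoder(
                rng,
                vocab_size=vocab_size,
                k=config.seq_k,
                d_model=config.seq_d_model,
                n_heads=config.seq_heads,
                n_layers=config.seq_layers,
                d_out=config.fusion_width,
                dropout_p=config.dropout,
            )
        if "graph" in self.channels:
            self.graph_encoder = GraphEncoder(
                rng,
                hidden=config.graph_hidden,
                message_size=config.graph_message_size,
                n_layers=config.graph_mp_layers,
                d_out=config.fusion_width,
                scalar_gate=config.graph_scalar_gate,
            )
        if "semantic" in self.channels:
            self.semantic_encoder = SemanticEncoder(
                rng,
                hidden=config.semantic_hidden,
                n_heads=config.semantic_heads,
                n_blocks=config.semantic_blocks,
                d_out=config.fusion_width,
                sampling_factor=config.probsparse_factor,
                full_attn_below=config.probsparse_full_below,
                dropout_p=config.dropout,
            )
        self.fusion = AttentionFusion(rng, width=config.fusion_width, d_att=config.fusion_att_dim)
        self.decoder = PairDecoder(
            rng,
            width=config.fusion_width,
            hidden1=config.decoder_hidden1,
            hidden2=config.decoder_hidden2,
            symmetric=config.symmetric_pairs,
        )

    def encode_drugs(self, batch: dict) -> tuple[Tensor, Tensor]:
        """Fused embeddings (U, width) and fusion coefficients (U, n_views)."""
        views: list[Tensor] = []
        if "seq" in self.channels:
            views.append(self.seq_encoder(batch["seq_ids"], batch["seq_len"]))
        if "graph" in self.channels:
            views.append(self.graph_encoder(batch["graph"]))
        if "semantic" in self.channels:
            views.append(self.semantic_encoder(batch["semantic"]))
        return self.fusion(views)

    def __call__(self, batch: dict) -> Tensor:
        fused, _ = self.encode_drugs(batch)
        f_i = fused.take_rows(batch["idx1"])
        f_j = fused.take_rows(batch["idx2"])
        return self.decoder(f_i, f_j)
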