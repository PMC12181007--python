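"""Splitting protocol, metrics, training loop and ablation machinery."""

import numpy as np
import pytest

from ddifuse.chem import PairRecord
from ddifuse.config import ABLATION_VARIANTS, ModelConfig
from ddifuse.errors import ConfigurationError, DatasetTooSmall, SingleClassTestSet
from ddifuse.train import (
    auroc,
    dedupe_pairs,
    evaluate_scores,
    run_experiment,
    run_single,
    split_dataset,
    load_checkpoint,
    save_checkpoint,
)


def _pairs(n):
    return [PairRecord(f"a{i}", f"b{i}", i % 2) for i in range(n)]


class TestSplits:
    def test_sizes_8_1_1(self):
        tr, va, te = split_dataset(_pairs(100), (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_fraction_subsamples_before_split(self):
        tr, va, te = split_dataset(_pairs(100), seed=0, fraction=0.5)
        assert len(tr) + len(va) + len(te) == 50

    def test_deterministic_and_exhaustive(self):
        a = split_dataset(_pairs(57), seed=3)
        b = split_dataset(_pairs(57), seed=3)
        assert a == b
        flat = [p for split in a for p in split]
        assert sorted(p.drug_id_1 for p in flat) == sorted(f"a{i}" for i in range(57))

    def test_unordered_dedup_prevents_leakage(self):
        pairs = [PairRecord("x", "y", 1), PairRecord("y", "x", 0)] + _pairs(20)
        assert len(dedupe_pairs(pairs)) == 21
        tr, va, te = split_dataset(pairs, seed=0)
        keys = [frozenset((p.drug_id_1, p.drug_id_2)) for s in (tr, va, te) for p in s]
        assert len(keys) == len(set(keys))

    def test_too_small_raises(self):
        with pytest.raises(DatasetTooSmall):
            split_dataset(_pairs(5))


class TestMetrics:
    def test_perfect_ranking(self):
        m = evaluate_scores(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert m == {"acc": 1.0, "f1": 1.0, "auroc": 1.0}

    def test_inverted_ranking(self):
        assert auroc(np.array([0.4, 0.6]), np.array([1, 0])) == 0.0

    def test_f1_from_counts(self):
        # TP=2, FP=1, FN=1 -> F1 = 2*2 / (2*2 + 1 + 1)
        scores = np.array([0.9, 0.9, 0.9, 0.1, 0.1])
        labels = np.array([1, 1, 0, 1, 0])
        m = evaluate_scores(scores, labels)
        assert abs(m["f1"] - 2 * 2 / (2 * 2 + 1 + 1)) < 1e-9

    def test_auroc_matches_rank_pair_oracle(self):
        """All-pairs comparison with half credit for ties, 200 random sets."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (len(pos) * len(neg))
            assert abs(auroc(scores, labels) - expected) < 1e-10

    def test_single_class_reported_missing(self):
        with pytest.raises(SingleClassTestSet):
            auroc(np.array([0.2, 0.4]), np.array([1, 1]))
        m = evaluate_scores(np.array([0.9, 0.8]), np.array([1, 1]))
        assert m["auroc"] is None


class TestTraining:
    def test_loss_decreases_and_deterministic(self, toy_drugs, toy_pairs, toy_vocab,
                                              tiny_config):
        m1, h1, model, feat = run_single(toy_drugs, toy_pairs, tiny_config, toy_vocab,
                                         seed=0)
        assert h1.train_loss[-1] < h1.train_loss[0]
        m2, h2, _, _ = run_single(toy_drugs, toy_pairs, tiny_config, toy_vocab, seed=0)
        assert h1.train_loss == h2.train_loss
        assert m1 == m2

    def test_gradients_reach_every_channel(self, toy_drugs, toy_pairs, toy_vocab,
                                           tiny_config):
        from ddifuse.fusion import bce_loss
        from ddifuse.model import DDIModel, DrugFeaturizer

        feat = DrugFeaturizer(toy_drugs, toy_vocab, tiny_config)
        model = DDIModel(np.random.default_rng(0), tiny_config, vocab_size=len(toy_vocab))
        chunk = toy_pairs[:8]
        batch = feat.collate_pairs(
            [(p.drug_id_1, p.drug_id_2) for p in chunk],
            labels=np.array([p.label for p in chunk], dtype=float),
        )
        loss = bce_loss(model(batch), batch["labels"])
        loss.backward()
        for channel_param in (
            model.seq_encoder.tok_emb.weight,
            model.graph_encoder.atom_emb.weight,
            model.semantic_encoder.atom_emb.weight,
        ):
            assert channel_param.grad is not None
            assert np.abs(channel_param.grad).sum() > 0

    def test_checkpoint_roundtrip(self, tmp_path, toy_drugs, toy_pairs, toy_vocab,
                                  tiny_config):
        from ddifuse.model import DrugFeaturizer
        from ddifuse.train import _predict

        _, _, model, feat = run_single(toy_drugs, toy_pairs, tiny_config, toy_vocab,
                                       seed=0)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, toy_vocab)
        restored, vocab2 = load_checkpoint(path)
        assert vocab2.tokens == toy_vocab.tokens
        feat2 = DrugFeaturizer(toy_drugs, vocab2, restored.config)
        p1 = _predict(model, feat, toy_pairs[:10])
        p2 = _predict(restored, feat2, toy_pairs[:10])
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestExperiments:
    def test_single_repeat_equals_run(self, toy_drugs, toy_pairs, toy_vocab,
                                      tiny_config):
        report = run_experiment(toy_drugs, toy_pairs, tiny_config, toy_vocab)
        assert len(report["runs"]) == 1
        assert report["mean_acc"] == report["runs"][0]["acc"]

    def test_no_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(channels=()).validate()

    def test_ablation_variants_match_protocol(self):
        assert set(ABLATION_VARIANTS) == {
            "full", "no_seq", "no_graph", "no_semantic",
            "seq_only", "graph_only", "semantic_only",
        }
        assert ABLATION_VARIANTS["no_seq"] == ("graph", "semantic")
        assert ABLATION_VARIANTS["no_graph"] == ("seq", "semantic")
        assert ABLATION_VARIANTS["no_semantic"] == ("seq", "graph")
        for name in ("seq", "graph", "semantic"):
            assert ABLATION_VARIANTS[f"{name}_only"] == (name,)
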