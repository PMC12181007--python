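"""Training and evaluation protocol.

Pairs are deduplicated as unordered pairs, optionally subsampled to a
fraction (robustness protocol), shuffled with a seeded generator and split
8:1:1 into train/validation/test.  The model is optimised with Adam
(learning rate 1e-4, batch size 16) under binary cross-entropy; the
checkpoint with the best validation AUROC is retained.  Metrics are
accuracy and F1 at threshold 0.5 and AUROC; experiments are repeated with
consecutive seeds and reported as per-run values plus their mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .chem import DrugRecord, PairRecord
from .config import ABLATION_VARIANTS, ModelConfig
from .errors import DatasetTooSmall, NaNLoss, SingleClassTestSet
from .fusion import bce_loss
from .model import DDIModel, DrugFeaturizer
from .nn import Adam
from .tokenizer import Vocabulary, build_vocabulary

logger = logging.getLogger("ddifuse")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------
def dedupe_pairs(pairs: list[PairRecord]) -> list[PairRecord]:
    """Drop repeated unordered pairs, keeping the first occurrence."""
    seen: set[frozenset] = set()
    out = []
    for p in pairs:
        key = frozenset((p.drug_id_1, p.drug_id_2))
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def split_dataset(
    pairs: list[PairRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    fraction: float = 1.0,
) -> tuple[list[PairRecord], list[PairRecord], list[PairRecord]]:
    """Seeded random split at floor boundaries; the remainder goes to train."""
    pairs = dedupe_pairs(pairs)
    rng = np.random.default_rng(seed)
    if fraction < 1.0:
        keep = rng.choice(len(pairs), size=int(round(fraction * len(pairs))), replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    if len(pairs) < 10:
        raise DatasetTooSmall(f"{len(pairs)} pairs after deduplication/subsampling")
    order = rng.permutation(len(pairs))
    n = len(pairs)
    n_valid, n_test = int(n * ratios[1]), int(n * ratios[2])
    n_train = n - n_valid - n_test
    shuffled = [pairs[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_valid],
        shuffled[n_train + n_valid :],
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC (ties counted half, Mann-Whitney form)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassTestSet("AUROC undefined on a single-class set")
    return float(roc_auc_score(labels, scores))


def evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> dict:
    preds = (np.asarray(scores) >= 0.5).astype(int)
    metrics = {
        "acc": float(accuracy_score(labels, preds)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
    }
    try:
        metrics["auroc"] = auroc(scores, labels)
    except SingleClassTestSet:
        metrics["auroc"] = None
    return metrics


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    valid_auroc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _predict(model: DDIModel, feat: DrugFeaturizer, pairs: list[PairRecord],
             batch_size: int = 64) -> np.ndarray:
    model.eval()
    out = []
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i : i + batch_size]
        batch = feat.collate_pairs([(p.drug_id_1, p.drug_id_2) for p in chunk])
        out.append(model(batch).data)
    model.train()
    return np.concatenate(out) if out else np.empty(0)


def train_model(
    model: DDIModel,
    feat: DrugFeaturizer,
    train_pairs: list[PairRecord],
    valid_pairs: list[PairRecord],
    config: ModelConfig,
    shuffle_seed: int = 0,
) -> TrainHistory:
    """Adam/BCE training with per-epoch validation and best-AUROC checkpointing."""
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(shuffle_seed)
    history = TrainHistory()
    best_auroc, best_state = -np.inf, None
    labels_valid = np.array([p.label for p in valid_pairs])
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            chunk = [train_pairs[i] for i in idx]
            batch = feat.collate_pairs(
                [(p.drug_id_1, p.drug_id_2) for p in chunk],
                labels=np.array([p.label for p in chunk], dtype=float),
            )
            probs = model(batch)
            loss = bce_loss(probs, batch["labels"])
            if not np.isfinite(loss.data):
                raise NaNLoss(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        history.train_loss.append(epoch_loss)
        if valid_pairs:
            scores = _predict(model, feat, valid_pairs)
            metrics = evaluate_scores(scores, labels_valid)
            va = metrics["auroc"] if metrics["auroc"] is not None else metrics["acc"]
            history.valid_auroc.append(va)
            if va > best_auroc:
                best_auroc, best_state = va, model.state_dict()
                history.best_epoch = epoch
            logger.info("epoch %d: train loss %.4f, valid AUROC %.4f", epoch, epoch_loss, va)
        else:
            logger.info("epoch %d: train loss %.4f", epoch, epoch_loss)
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return history


def evaluate_model(
    model: DDIModel, feat: DrugFeaturizer, test_pairs: list[PairRecord]
) -> dict:
    scores = _predict(model, feat, test_pairs)
    labels = np.array([p.label for p in test_pairs])
    return evaluate_scores(scores, labels)


# ---------------------------------------------------------------------------
# repeated experiments / ablations
# ---------------------------------------------------------------------------
def run_single(
    drugs: list[DrugRecord],
    pairs: list[PairRecord],
    config: ModelConfig,
    vocab: Vocabulary,
    seed: int,
) -> tuple[dict, TrainHistory, DDIModel, DrugFeaturizer]:
    train_p, valid_p, test_p = split_dataset(
        pairs, config.split_ratios, seed=seed, fraction=config.dataset_fraction
    )
    feat = DrugFeaturizer(drugs, vocab, config)
    model = DDIModel(np.random.default_rng(seed), config, vocab_size=len(vocab))
    history = train_model(model, feat, train_p, valid_p, config, shuffle_seed=seed)
    metrics = evaluate_model(model, feat, test_p)
    metrics["split_sizes"] = (len(train_p), len(valid_p), len(test_p))
    return metrics, history, model, feat


def run_experiment(
    drugs: list[DrugRecord],
    pairs: list[PairRecord],
    config: ModelConfig,
    vocab: Vocabulary | None = None,
) -> dict:
    """Repeat training ``config.n_repeats`` times (seeds seed+i) and average."""
    config.validate()
    if vocab is None:
        vocab = build_vocabulary(
            [d.smiles for d in drugs],
            max_merges=config.vocab_max_merges,
            min_frequency=config.vocab_min_frequency,
        )
    runs = []
    for i in range(config.n_repeats):
        metrics, history, _, _ = run_single(drugs, pairs, config, vocab, seed=config.seed + i)
        metrics["final_train_loss"] = history.train_loss[-1]
        runs.append(metrics)
    report = {"runs": runs, "config": config.to_dict()}
    for key in ("acc", "f1", "auroc", "final_train_loss"):
        vals = [r[key] for r in runs if r[key] is not None]
        report[f"mean_{key}"] = float(np.mean(vals)) if vals else None
    return report


def run_ablation(
    drugs: list[DrugRecord],
    pairs: list[PairRecord],
    config: ModelConfig,
    vocab: Vocabulary | None = None,
) -> dict[str, dict]:
    """Run the seven channel-toggle variants and collect their reports."""
    if vocab is None:
        vocab = build_vocabulary(
            [d.smiles for d in drugs],
            max_merges=config.vocab_max_merges,
            min_frequency=config.vocab_min_frequency,
        )
    results = {}
    for name, channels in ABLATION_VARIANTS.items():
        results[name] = run_experiment(drugs, pairs, config.with_channels(channels), vocab)
    return results


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------
def save_checkpoint(path, model: DDIModel, vocab: Vocabulary) -> None:
    """Single-file checkpoint: parameters + config + vocabulary."""
    meta = {
        "config": model.config.to_dict(),
        "vocab": {
            "tokens": vocab.tokens,
            "frequencies": vocab.frequencies,
            "merges": [list(m) for m in vocab.merges],
            "max_merges": vocab.max_merges,
            "min_frequency": vocab.min_frequency,
        },
    }
    state = model.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[DDIModel, Vocabulary]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    config = ModelConfig.from_dict(meta["config"])
    v = meta["vocab"]
    vocab = Vocabulary(
        tokens=v["tokens"],
        frequencies=v["frequencies"],
        merges=[tuple(m) for m in v["merges"]],
        max_merges=v["max_merges"],
        min_frequency=v["min_frequency"],
    )
    model = DDIModel(np.random.default_rng(0), config, vocab_size=len(vocab))
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    model.eval()
    return model, vocab
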