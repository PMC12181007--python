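"""Frequent-consecutive-subsequence tokenisation of SMILES strings.

A SMILES string is first split into base symbols (multi-character element
symbols, bracket atoms, two-digit ring closures and single characters); a
vocabulary of frequent contiguous subsequences is then mined by greedy
merging of the most frequent adjacent symbol pair, byte-pair-encoding style.
Merged tokens are "medium-sized substructures" — contiguous SMILES substrings
such as ``C(=O)O`` — and merges never span the ``.`` fragment separator.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .errors import EmptyCorpus, UnparsableSmiles

PAD, UNK = 0, 1
PAD_TOKEN, UNK_TOKEN = "<pad>", "<unk>"

# bracket atoms first, then two-character organic-subset elements, then
# two-digit ring closures, then any single character
_BASE_RE = re.compile(r"\[[^\[\]]*\]|Cl|Br|%\d{2}|.")


def base_tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into base symbols.

    The concatenation of the returned tokens reproduces the input exactly.
    Unbalanced square brackets raise :class:`UnparsableSmiles`.
    """
    if not smiles:
        raise UnparsableSmiles("empty SMILES string")
    tokens = _BASE_RE.findall(smiles)
    if any(t in ("[", "]") for t in tokens):
        raise UnparsableSmiles(f"unbalanced brackets in {smiles!r}")
    return tokens


@dataclass
class Vocabulary:
    """Token vocabulary with merge history.

    ``tokens[i]`` is the string for id ``i``; ids 0 and 1 are reserved for
    PAD and UNK.  ``merges`` records, in creation order, the adjacent pairs
    merged during mining together with the pair frequency at that step.
    """

    tokens: list[str]
    frequencies: list[int]
    merges: list[tuple[str, str, int]]
    max_merges: int
    min_frequency: int
    token_to_id: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.token_to_id:
            self.token_to_id = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TokenSequence:
    """Fixed-length padded/truncated sequence of token ids."""

    ids: list[int]
    true_length: int

    def __post_init__(self):
        assert all(i == PAD for i in self.ids[self.true_length:])


def _segments(tokens: list[str]) -> list[list[str]]:
    """Split a token list at the fragment separator '.' (separators kept)."""
    segs: list[list[str]] = [[]]
    for t in tokens:
        if t == ".":
            segs.append([t])
            segs.append([])
        else:
            segs[-1].append(t)
    return segs


def _count_pairs(seqs: list[list[str]]) -> Counter:
    counts: Counter = Counter()
    for seq in seqs:
        for seg in _segments(seq):
            for a, b in zip(seg, seg[1:]):
                counts[(a, b)] += 1
    return counts


def _apply_merge(seq: list[str], pair: tuple[str, str]) -> list[str]:
    a, b = pair
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == a and seq[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def build_vocabulary(
    corpus: list[str], max_merges: int = 3000, min_frequency: int = 2
) -> Vocabulary:
    """Mine a frequent-subsequence vocabulary from a SMILES corpus.

    Greedily merges the most frequent adjacent token pair (ties broken by
    lexicographic pair order) until ``max_merges`` merges have been made or
    no pair occurs at least ``min_frequency`` times.  Deterministic: the same
    corpus and parameters always produce the same vocabulary.
    """
    if not corpus:
        raise EmptyCorpus("vocabulary construction needs at least one SMILES")
    seqs = [base_tokenize(s) for s in corpus]
    base_counts: Counter = Counter(t for seq in seqs for t in seq)
    merges: list[tuple[str, str, int]] = []
    for _ in range(max_merges):
        pair_counts = _count_pairs(seqs)
        if not pair_counts:
            break
        best = min(pair_counts, key=lambda p: (-pair_counts[p], p))
        if pair_counts[best] < min_frequency:
            break
        merges.append((best[0], best[1], pair_counts[best]))
        seqs = [_apply_merge(seq, best) for seq in seqs]
    final_counts: Counter = Counter(t for seq in seqs for t in seq)
    tokens = [PAD_TOKEN, UNK_TOKEN]
    frequencies = [0, 0]
    for t in sorted(base_counts):
        tokens.append(t)
        frequencies.append(final_counts.get(t, 0))
    for a, b, _ in merges:
        tok = a + b
        if tok not in tokens:  # distinct merge steps can produce equal strings
            tokens.append(tok)
            frequencies.append(final_counts.get(tok, 0))
    return Vocabulary(
        tokens=tokens,
        frequencies=frequencies,
        merges=merges,
        max_merges=max_merges,
        min_frequency=min_frequency,
    )


def tokenize(smiles: str, vocab: Vocabulary) -> list[str]:
    """Decompose a SMILES into vocabulary tokens by replaying the merges."""
    seq = base_tokenize(smiles)
    for a, b, _ in vocab.merges:
        seq = _apply_merge(seq, (a, b))
    return seq

def encode(smiles: str, vocab: Vocabulary, k: int = 50) -> TokenSequence:
    """Encode a SMILES as a fixed-length id sequence.

    Sequences longer than ``k`` are truncated; shorter ones are padded with
    PAD (id 0).  Base symbols missing from the vocabulary map to UNK.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    toks = tokenize(smiles, vocab)
    ids = [vocab.token_to_id.get(t, UNK) for t in toks][:k]
    true_length = len(ids)
    ids = ids + [PAD] * (k - true_length)
    return TokenSequence(ids=ids, true_length=true_length)


def decode(seq: TokenSequence, vocab: Vocabulary) -> str:
    """Concatenate token strings, skipping PAD; UNK raises (not invertible)."""
    parts = []
    for i in seq.ids[: seq.true_length]:
        if i == UNK:
            raise ValueError("sequence contains UNK; decoding is lossy")
        parts.append(vocab.tokens[i])
    return "".join(parts)


# ---------------------------------------------------------------------------
# vocabulary file format: header lines, then token<TAB>id<TAB>frequency
# ---------------------------------------------------------------------------
def save_vocabulary(path, vocab: Vocabulary) -> None:
    with open(path, "w") as fh:
        fh.write(f"#max_merges\t{vocab.max_merges}\n")
        fh.write(f"#min_frequency\t{vocab.min_frequency}\n")
        for a, b, freq in vocab.merges:
            fh.write(f"#merge\t{a}\t{b}\t{freq}\n")
        for tok, i, freq in zip(vocab.tokens, range(len(vocab)), vocab.frequencies):
            fh.write(f"{tok}\t{i}\t{freq}\n")


def load_vocabulary(path) -> Vocabulary:
    merges: list[tuple[str, str, int]] = []
    tokens: list[str] = []
    frequencies: list[int] = []
    max_merges = min_frequency = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "#max_merges":
                max_merges = int(parts[1])
            elif parts[0] == "#min_frequency":
                min_frequency = int(parts[1])
            elif parts[0] == "#merge":
                merges.append((parts[1], parts[2], int(parts[3])))
            else:
                tok, idx, freq = parts
                assert int(idx) == len(tokens)
                tokens.append(tok)
                frequencies.append(int(freq))
    return Vocabulary(
        tokens=tokens,
        frequencies=frequencies,
        merges=merges,
        max_merges=max_merges,
        min_frequency=min_frequency,
    )
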