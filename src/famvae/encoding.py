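"""One-hot encoding, similarity weighting, train/test splitting and the
weighted-with-replacement batch stream that feeds model training.

Sequences are represented as (L, 21) one-hot matrices over the fixed
alphabet (20 amino acids + gap). Training weights are the fraction of
sequence identity to the designated wildtype raised to a power (default
2.25), which down-weights distant homologs so batches are enriched in
near-wildtype sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, ALPHABET_SIZE, indices_of
from .curation import Alignment

__all__ = [
    "WeightingConfig",
    "SplitConfig",
    "one_hot_encode",
    "encode_alignment",
    "decode_one_hot",
    "sequence_identity",
    "training_weights",
    "split_train_test",
    "weighted_batches",
    "export_weights_and_split",
]


@dataclass(frozen=True)
class WeightingConfig:
    """Similarity-weighting parameters: weight_i = identity(seq_i, ref)^exponent."""

    exponent: float = 2.25
    reference_id: str | None = None  # None -> the alignment's target

    def __post_init__(self) -> None:
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.10
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


def one_hot_encode(seq: str, alphabet: str = ALPHABET) -> np.ndarray:
    """(L, |A|) binary matrix with exactly one 1 per position."""
    if alphabet == ALPHABET:
        idx = indices_of(seq)
    else:
        lookup = {a: i for i, a in enumerate(alphabet)}
        try:
            idx = np.array([lookup[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            pos = next(i for i, c in enumerate(seq) if c not in lookup)
            raise ValueError(
                f"letter {seq[pos]!r} at position {pos} not in alphabet"
            ) from exc
    out = np.zeros((len(seq), len(alphabet)), dtype=np.float32)
    out[np.arange(len(seq)), idx] = 1.0
    return out


def encode_alignment(aln: Alignment) -> np.ndarray:
    """(N, L, 21) stack of one-hot matrices in alignment order."""
    idx = aln.to_indices()
    out = np.zeros((aln.depth, aln.width, ALPHABET_SIZE), dtype=np.float32)
    n = np.arange(aln.depth)[:, None]
    l = np.arange(aln.width)[None, :]
    out[n, l, idx] = 1.0
    return out


def decode_one_hot(mat: np.ndarray, alphabet: str = ALPHABET) -> str:
    """Argmax decode of a (L, |A|) matrix (one-hot or probabilities)."""
    letters = np.array(list(alphabet))
    return "".join(letters[np.argmax(mat, axis=-1)])


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical columns over the full width.

    Gap-gap columns count as matches, gap-letter as mismatches; the
    denominator is the alignment width.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def training_weights(aln: Alignment, cfg: WeightingConfig | None = None) -> np.ndarray:
    """Per-sequence sampling weights identity^exponent (reference weight 1)."""
    cfg = cfg or WeightingConfig()
    ref_id = cfg.reference_id or aln.target_id
    ref = aln.row(ref_id)
    ident = np.array([sequence_identity(r, ref) for r in aln.rows])
    return ident ** cfg.exponent


def split_train_test(aln: Alignment, cfg: SplitConfig) -> tuple[list[str], list[str]]:
    """Seed-reproducible disjoint exhaustive split; target forced into train."""
    if aln.depth < 10:
        raise ValueError("need at least 10 sequences to split")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(aln.depth)
    n_test = int(round(aln.depth * cfg.test_fraction))
    n_test = min(max(n_test, 1), aln.depth - 1)
    test = list(order[:n_test])
    train = list(order[n_test:])
    ti = aln.target_index
    if ti in test:
        test.remove(ti)
        swapped = train.pop(0)
        test.append(swapped)
        train.append(ti)
    return [aln.ids[i] for i in train], [aln.ids[i] for i in test]


def weighted_batches(
    ids: Sequence[str] | Sequence[int],
    weights: np.ndarray,
    batch_size: int,
    seed: int,
    n_batches: int | None = None,
) -> Iterator[np.ndarray]:
    """Stream of index batches drawn i.i.d. with replacement, P(i) ∝ weight_i.

    Yields arrays of positions into ``ids`` (not the ids themselves), so the
    caller can index its encoded data directly. Runs forever unless
    ``n_batches`` is given.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(ids):
        raise ValueError("weights and ids must have equal length")
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    p = weights / total
    rng = np.random.default_rng(seed)
    produced = 0
    while n_batches is None or produced < n_batches:
        yield rng.choice(len(ids), size=batch_size, replace=True, p=p)
        produced += 1


def export_weights_and_split(
    aln: Alignment,
    weights: np.ndarray,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    path: str | Path,
) -> pd.DataFrame:
    """TSV of (id, weight, split) for record-keeping."""
    split = {sid: "train" for sid in train_ids}
    split.update({sid: "test" for sid in test_ids})
    df = pd.DataFrame(
        {"id": aln.ids, "weight": weights, "split": [split[s] for s in aln.ids]}
    )
    df.to_csv(path, sep="\t", index=False)
    return df
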