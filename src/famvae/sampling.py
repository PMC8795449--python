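"""Near-wildtype variant generation from a trained model.

The wildtype (target) is encoded once; latent vectors are then drawn from
N(mu, scale * diag(sigma^2)) at progressively larger variance multipliers and
argmax-decoded back to sequences. Small scales yield the maximum a posteriori
sequence (few or no mutations); larger scales drift further from the target.
The sweep deduplicates sequences, names each variant's mutations in 1-based
wildtype coordinates ("S60A" for substitutions, "ΔK70" for deletions), and
stops once a scale produces any sequence over the mutation cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP
from .encoding import decode_one_hot, one_hot_encode
from .vae import LatentEncoding, SequenceVAE

__all__ = [
    "SamplingSchedule",
    "Variant",
    "VariantSet",
    "encode_target",
    "sample_at_scale",
    "sample_sequences",
    "variance_sweep",
    "mutation_calls",
    "apply_mutations",
    "latent_distance",
    "hamming_distance",
]

DEFAULT_SCALES: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class SamplingSchedule:
    """Variance sweep parameters.

    ``scales`` multiply the posterior variance (or the standard deviation when
    ``scale_sigma`` is set); ``max_mutations`` caps the Hamming distance of a
    retained variant (16 in the full-scale configuration, ~5% of the length).
    """

    scales: tuple[float, ...] = DEFAULT_SCALES
    samples_per_scale: int = 100
    max_mutations: int = 16
    max_variants: int | None = None
    seed: int = 0
    scale_sigma: bool = False
    stop_on_overflow: bool = True

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.scales):
            raise ValueError("scales must be nonnegative")
        if list(self.scales) != sorted(self.scales):
            raise ValueError("scales must be sorted ascending")
        if self.samples_per_scale < 1 or self.max_mutations < 1:
            raise ValueError("samples_per_scale and max_mutations must be >= 1")


@dataclass
class Variant:
    sequence: str  # alignment-width row (gap letters = deletions)
    mutations: list[str]
    hamming: int
    scale: float

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass
class VariantSet:
    target: str
    variants: list[Variant] = field(default_factory=list)
    per_scale_counts: dict[float, dict[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def sequences(self) -> list[str]:
        return [v.sequence for v in self.variants]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [f"v{i + 1:04d}" for i in range(len(self.variants))],
                "scale": [v.scale for v in self.variants],
                "hamming": [v.hamming for v in self.variants],
                "mutations": [",".join(v.mutations) for v in self.variants],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(v.ungapped), id=f"v{i + 1:04d}",
                      description=f"scale={v.scale} hamming={v.hamming}")
            for i, v in enumerate(self.variants)
        ]
        seqio_write(records, str(path), "fasta")


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


def latent_distance(z1: np.ndarray, z2: np.ndarray) -> float:
    """Euclidean distance between two latent vectors."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError(f"dimension mismatch: {z1.shape} vs {z2.shape}")
    return float(np.linalg.norm(z1 - z2))


def encode_target(model: SequenceVAE, target_row: str) -> LatentEncoding:
    """Deterministic posterior parameters of the wildtype sequence."""
    if len(target_row) != model.cfg.L:
        raise ValueError(
            f"target length {len(target_row)} != model width {model.cfg.L}"
        )
    x = one_hot_encode(target_row, model.cfg.alphabet)[None]
    enc = model.encode(x, train=False)
    return LatentEncoding(mu=enc.mu[0], log_var=enc.log_var[0])


def sample_at_scale(
    model: SequenceVAE,
    enc: LatentEncoding,
    scale: float,
    n: int,
    seed: int,
    scale_sigma: bool = False,
) -> list[str]:
    """Draw n latent vectors around ``enc`` and argmax-decode them.

    ``scale`` multiplies the posterior variance by default; with
    ``scale_sigma`` it multiplies the standard deviation instead. Scale 0
    decodes the posterior mean (MAP sequence) n times.
    """
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma = np.exp(0.5 * enc.log_var)
    factor = scale if scale_sigma else np.sqrt(scale)
    eps = rng.standard_normal((n, enc.mu.shape[-1]))
    z = enc.mu[None, :] + factor * sigma[None, :] * eps
    out: list[str] = []
    for start in range(0, n, 256):
        probs = model.decode(z[start:start + 256], train=False)
        out.extend(decode_one_hot(p, model.cfg.alphabet) for p in probs)
    return out


def sample_sequences(
    model: SequenceVAE,
    n: int,
    seed: int,
    decode: str = "sample",
) -> list[str]:
    """Draw n sequences from the generative model (z ~ N(0, I) prior).

    ``decode="sample"`` draws each position from the decoder's categorical
    distribution (appropriate for distribution-matching diagnostics);
    ``decode="argmax"`` takes the modal letter instead.
    """
    if decode not in ("sample", "argmax"):
        raise ValueError("decode must be 'sample' or 'argmax'")
    rng = np.random.default_rng(seed)
    letters = np.array(list(model.cfg.alphabet))
    out: list[str] = []
    for start in range(0, n, 256):
        m = min(256, n - start)
        z = rng.standard_normal((m, model.cfg.latent_dim))
        probs = model.decode(z, train=False)
        if decode == "argmax":
            idx = probs.argmax(axis=-1)
        else:
            cdf = probs.cumsum(axis=-1)
            u = rng.random(probs.shape[:-1])[..., None]
            idx = (u > cdf).sum(axis=-1)
        out.extend("".join(letters[row]) for row in idx)
    return out


def mutation_calls(variant_row: str, target_row: str) -> list[str]:
    """Name every difference in 1-based wildtype coordinates.

    Substitutions are "XnY"; a gap in the variant at wildtype letter X,
    position n, is the deletion "ΔXn". The wildtype row must be gap-free
    (slice the alignment to the target first).
    """
    if len(variant_row) != len(target_row):
        raise ValueError("variant and target must have equal width")
    if GAP in target_row:
        raise ValueError("target row must be gap-free (slice to target first)")
    calls: list[str] = []
    for pos, (t, v) in enumerate(zip(target_row, variant_row), start=1):
        if t == v:
            continue
        calls.append(f"Δ{t}{pos}" if v == GAP else f"{t}{pos}{v}")
    return calls


def apply_mutations(target_row: str, mutations: Iterable[str]) -> str:
    """Inverse of :func:`mutation_calls`: rebuild the variant row."""
    row = list(target_row)
    for name in mutations:
        if name.startswith("Δ"):
            pos = int(name[2:])
            expected = name[1]
            new = GAP
        else:
            pos = int(name[1:-1])
            expected = name[0]
            new = name[-1]
        if target_row[pos - 1] != expected:
            raise ValueError(
                f"mutation {name}: wildtype has {target_row[pos - 1]!r} at "
                f"position {pos}"
            )
        row[pos - 1] = new
    return "".join(row)


def variance_sweep(
    model: SequenceVAE,
    target_row: str,
    sched: SamplingSchedule,
) -> VariantSet:
    """Iterate the variance schedule collecting deduplicated variants.

    Sequences identical to the target are skipped; sequences above the
    mutation cap are dropped, and (by default) the sweep stops at the first
    scale that produces any over-cap sequence. The first occurrence of a
    sequence fixes its recorded scale.
    """
    enc = encode_target(model, target_row)
    result = VariantSet(target=target_row)
    seen: set[str] = set()
    for i, scale in enumerate(sched.scales):
        n = 1 if scale == 0 else sched.samples_per_scale
        seqs = sample_at_scale(
            model, enc, scale, n, seed=sched.seed + i,
            scale_sigma=sched.scale_sigma,
        )
        tally = {"sampled": len(seqs), "kept": 0, "duplicate": 0,
                 "is_target": 0, "over_cap": 0}
        overflow = False
        for seq in seqs:
            if seq == target_row:
                tally["is_target"] += 1
                continue
            h = hamming_distance(seq, target_row)
            if h > sched.max_mutations:
                tally["over_cap"] += 1
                overflow = True
                continue
            if seq in seen:
                tally["duplicate"] += 1
                continue
            seen.add(seq)
            tally["kept"] += 1
            result.variants.append(
                Variant(
                    sequence=seq,
                    mutations=mutation_calls(seq, target_row),
                    hamming=h,
                    scale=scale,
                )
            )
            if (sched.max_variants is not None
                    and len(result.variants) >= sched.max_variants):
                result.per_scale_counts[scale] = tally
                return result
        result.per_scale_counts[scale] = tally
        if overflow and sched.stop_on_overflow:
            break
    return result
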