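"""Consensus sequence design — the classical engineering control.

The consensus sequence takes, at every alignment column, the most frequent
non-gap letter (ties broken by fixed alphabet order). The substitutions that
convert the wildtype into the consensus define a combinatorial library: each
substitution is independently on or off, giving 2^k variants including the
unmodified wildtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .alphabet import ALPHABET, GAP
from .curation import Alignment
from .encoding import encode_alignment

__all__ = [
    "ConsensusDesign",
    "consensus_sequence",
    "consensus_substitutions",
    "enumerate_library",
    "design_consensus",
]

_FULL_ENUMERATION_GUARD = 25


@dataclass
class ConsensusDesign:
    consensus: str
    substitutions: list[tuple[int, str, str]]  # (1-based position, target, consensus)

    @property
    def library_size(self) -> int:
        return 2 ** len(self.substitutions)

    @property
    def substitution_names(self) -> list[str]:
        return [f"{t}{pos}{c}" for pos, t, c in self.substitutions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.substitutions, columns=["position", "target", "consensus"]
        )


def consensus_sequence(aln: Alignment) -> str:
    """Most frequent non-gap letter per column; alphabet-order tie-break."""
    counts = encode_alignment(aln).sum(axis=0)  # (L, 21)
    aa_counts = counts[:, :-1]  # drop the gap letter from the election
    if (aa_counts.sum(axis=1) == 0).any():
        col = int(np.argmax(aa_counts.sum(axis=1) == 0))
        raise ValueError(f"column {col} is entirely gaps; no consensus letter")
    # argmax returns the first maximum, i.e. the earliest letter in ALPHABET
    best = aa_counts.argmax(axis=1)
    return "".join(ALPHABET[i] for i in best)


def consensus_substitutions(
    consensus: str, target: str
) -> list[tuple[int, str, str]]:
    """Ordered (position, target letter, consensus letter) for every difference."""
    if len(consensus) != len(target):
        raise ValueError("consensus and target must have equal width")
    return [
        (pos, t, c)
        for pos, (t, c) in enumerate(zip(target, consensus), start=1)
        if t != c
    ]


def enumerate_library(
    target: str,
    substitutions: list[tuple[int, str, str]],
    mode: str = "full",
    n: int | None = None,
    seed: int = 0,
) -> list[str]:
    """All (or a uniform sample of) on/off combinations of the substitutions.

    Full mode returns all 2^k variants, the unmodified target first, then in
    binary-counter order over the substitution bits. Sample mode draws ``n``
    distinct combinations uniformly without replacement, seed-reproducibly.
    """
    k = len(substitutions)
    for pos, t, c in substitutions:
        if target[pos - 1] != t:
            raise ValueError(
                f"substitution {t}{pos}{c}: target has {target[pos - 1]!r}"
            )
        if c == GAP:
            raise ValueError("consensus substitutions cannot introduce gaps")
    if mode == "full":
        if k > _FULL_ENUMERATION_GUARD:
            raise ValueError(
                f"refusing full enumeration of 2^{k} variants; use mode='sample'"
            )
        masks = range(2 ** k)
    elif mode == "sample":
        if n is None:
            raise ValueError("sample mode requires n")
        if n > 2 ** k:
            raise ValueError(f"cannot draw {n} distinct variants from 2^{k}")
        rng = np.random.default_rng(seed)
        if k <= _FULL_ENUMERATION_GUARD:
            masks = rng.choice(2 ** k, size=n, replace=False).tolist()
        else:
            chosen: set[int] = set()
            while len(chosen) < n:
                bits = rng.integers(0, 2, size=k)
                chosen.add(int("".join(map(str, bits)), 2))
            masks = sorted(chosen)
    else:
        raise ValueError("mode must be 'full' or 'sample'")

    out: list[str] = []
    for mask in masks:
        row = list(target)
        for bit, (pos, _t, c) in enumerate(substitutions):
            if mask >> bit & 1:
                row[pos - 1] = c
        out.append("".join(row))
    return out


def design_consensus(aln: Alignment) -> ConsensusDesign:
    """Consensus sequence plus its substitution list relative to the target."""
    cons = consensus_sequence(aln)
    target = aln.target_row
    if GAP in target:
        raise ValueError("target row must be gap-free (slice to target first)")
    return ConsensusDesign(
        consensus=cons, substitutions=consensus_substitutions(cons, target)
    )


def write_library_fasta(variants: list[str], path: str | Path,
                        prefix: str = "c") -> None:
    records = [
        SeqRecord(Seq(v), id=f"{prefix}{i + 1:04d}", description="")
        for i, v in enumerate(variants)
    ]
    seqio_write(records, str(path), "fasta")
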