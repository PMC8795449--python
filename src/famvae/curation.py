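"""Multiple-sequence-alignment curation.

A family alignment pulled from public databases contains homologs that
distort the alignment (long insertions forcing gap-heavy columns), fragments,
and mis-annotated records. This module scores each sequence's "gappiness"
(the sum of column gap fractions over the columns where that sequence itself
is gapped, counting only columns whose gap fraction exceeds a threshold *w*),
removes high-scoring sequences, short sequences and off-description records,
and finally slices the alignment columns down to the target's ungapped
positions so that coordinates match the wildtype protein.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALPHABET, AMBIGUOUS_LETTERS, GAP, indices_of

__all__ = [
    "Alignment",
    "GappinessParams",
    "CurationReport",
    "read_alignment",
    "write_alignment",
    "gappiness_scores",
    "filter_alignment",
    "slice_to_target",
]


@dataclass
class Alignment:
    """A rectangular protein alignment over ``ALPHABET`` with a designated target.

    ``rows`` are equal-length strings; ``target_id`` names the wildtype
    sequence the family is anchored to (it must be present in ``ids``).
    """

    ids: list[str]
    rows: list[str]
    target_id: str
    descriptions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence identifiers must be unique")
        if not self.rows:
            raise ValueError("alignment is empty")
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length {len(row)}, "
                    f"expected {width}"
                )
        if self.target_id not in self.ids:
            raise ValueError(f"target id {self.target_id!r} not in alignment")
        if not self.descriptions:
            self.descriptions = ["" for _ in self.ids]
        for sid, row in zip(self.ids, self.rows):
            indices_of(row)  # raises on out-of-alphabet letters

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def target_index(self) -> int:
        return self.ids.index(self.target_id)

    @property
    def target_row(self) -> str:
        return self.rows[self.target_index]

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def to_indices(self) -> np.ndarray:
        """Integer matrix (depth, width) of letter indices, gap = 20."""
        return np.stack([indices_of(r) for r in self.rows])

    def subset(self, keep: Iterable[int]) -> "Alignment":
        keep = list(keep)
        return Alignment(
            ids=[self.ids[i] for i in keep],
            rows=[self.rows[i] for i in keep],
            target_id=self.target_id,
            descriptions=[self.descriptions[i] for i in keep],
        )


@dataclass(frozen=True)
class GappinessParams:
    """Curation thresholds.

    w
        Column gap-fraction threshold in [0, 1]; a column contributes to a
        sequence's gappiness only when its gap fraction strictly exceeds w.
    score_cutoff
        Sequences with gappiness score s_i > score_cutoff are removed.
    min_ungapped_length
        Sequences whose ungapped length falls below this are removed.
    description_keyword
        Optional case-sensitive substring a record description must contain.
    """

    w: float = 0.9
    score_cutoff: float = 10.0
    min_ungapped_length: int = 290
    description_keyword: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.score_cutoff <= 0:
            raise ValueError("score_cutoff must be positive")
        if self.min_ungapped_length <= 0:
            raise ValueError("min_ungapped_length must be positive")


@dataclass
class CurationReport:
    n_input: int = 0
    n_removed_gappy: int = 0
    n_removed_short: int = 0
    n_removed_keyword: int = 0
    n_output: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    sliced_columns: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            f"input sequences      : {self.n_input}",
            f"removed (gappy)      : {self.n_removed_gappy}",
            f"removed (short)      : {self.n_removed_short}",
            f"removed (keyword)    : {self.n_removed_keyword}",
            f"output sequences     : {self.n_output}",
        ]
        if self.sliced_columns:
            lines.append(f"sliced columns (0-based): {len(self.sliced_columns)}")
        return "\n".join(lines)


def read_alignment(
    path: str | Path,
    target_id: str,
    ambiguous: str = "reject",
) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Letters are uppercased and ``.`` is normalized to ``-``. Ambiguity codes
    (B, J, X, Z, U, O) are rejected by default; ``ambiguous="gap"`` maps them
    to the gap letter instead.
    """
    if ambiguous not in ("reject", "gap"):
        raise ValueError("ambiguous must be 'reject' or 'gap'")
    ids: list[str] = []
    rows: list[str] = []
    descriptions: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        row = str(rec.seq).upper().replace(".", GAP)
        if ambiguous == "gap":
            for letter in AMBIGUOUS_LETTERS:
                row = row.replace(letter, GAP)
        ids.append(rec.id)
        rows.append(row)
        descriptions.append(rec.description)
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        bad = next(sid for sid, r in zip(ids, rows) if len(r) != len(rows[0]))
        raise ValueError(f"ragged alignment: record {bad!r} differs in length")
    if target_id not in ids:
        raise ValueError(f"target id {target_id!r} not found in {path}")
    return Alignment(ids=ids, rows=rows, target_id=target_id,
                     descriptions=descriptions)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description=desc)
        for sid, row, desc in zip(aln.ids, aln.rows, aln.descriptions)
    ]
    SeqIO.write(records, str(path), "fasta")


def gappiness_scores(aln: Alignment, w: float = 0.9) -> np.ndarray:
    """Per-sequence gappiness s_i = sum of column gap fractions over the
    columns where sequence i is gapped, counting only columns whose gap
    fraction strictly exceeds ``w``.

    Columns at exactly fraction ``w`` contribute nothing (strict inequality).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    gap_mask = aln.to_indices() == len(ALPHABET) - 1  # (N, L)
    col_frac = gap_mask.mean(axis=0)
    contrib = np.where(col_frac > w, col_frac, 0.0)
    return gap_mask @ contrib


def filter_alignment(
    aln: Alignment, params: GappinessParams
) -> tuple[Alignment, CurationReport]:
    """Remove gappy, short, and off-description sequences (in that order).

    Gap fractions are computed once on the input alignment; removals do not
    trigger re-scoring. The target sequence must survive every filter.
    """
    report = CurationReport(n_input=aln.depth)
    scores = gappiness_scores(aln, params.w)

    gappy = scores > params.score_cutoff
    ungapped_len = np.array([len(r.replace(GAP, "")) for r in aln.rows])
    short = (~gappy) & (ungapped_len < params.min_ungapped_length)
    if params.description_keyword is not None:
        kw = params.description_keyword
        off = np.array([kw not in d for d in aln.descriptions])
    else:
        off = np.zeros(aln.depth, dtype=bool)
    off &= ~(gappy | short)

    ti = aln.target_index
    for mask, reason in ((gappy, "gappy"), (short, "short"), (off, "keyword")):
        if mask[ti]:
            raise ValueError(
                f"target {aln.target_id!r} would be removed by the "
                f"{reason!r} filter; adjust parameters"
            )

    keep = ~(gappy | short | off)
    if not keep.any():
        raise ValueError("all sequences removed; nothing left to align")

    report.n_removed_gappy = int(gappy.sum())
    report.n_removed_short = int(short.sum())
    report.n_removed_keyword = int(off.sum())
    report.removed_ids = {
        "gappy": [aln.ids[i] for i in np.flatnonzero(gappy)],
        "short": [aln.ids[i] for i in np.flatnonzero(short)],
        "keyword": [aln.ids[i] for i in np.flatnonzero(off)],
    }
    out = aln.subset(np.flatnonzero(keep))
    report.n_output = out.depth
    return out, report


def slice_to_target(aln: Alignment) -> tuple[Alignment, CurationReport]:
    """Drop every column where the target row carries a gap.

    After slicing the target row is gap-free and its columns are the
    wildtype's residue coordinates; other rows may still contain gaps
    (deletions relative to the target).
    """
    target = aln.target_row
    dropped = [j for j, letter in enumerate(target) if letter == GAP]
    keep = [j for j in range(aln.width) if target[j] != GAP]
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    out = Alignment(
        ids=list(aln.ids),
        rows=rows,
        target_id=aln.target_id,
        descriptions=list(aln.descriptions),
    )
    report = CurationReport(
        n_input=aln.depth, n_output=out.depth, sliced_columns=dropped
    )
    return out, report
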