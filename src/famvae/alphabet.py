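"""Protein alphabet shared by every module.

The alignment alphabet is the 20 standard amino acids followed by the gap
letter, in a fixed order that is serialized with every model checkpoint so
that one-hot encodings are portable.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP
ALPHABET_SIZE: int = len(ALPHABET)  # 21

#: Ambiguity / rare codes that may appear in public sequence records.
AMBIGUOUS_LETTERS: frozenset[str] = frozenset("BJXZUO")

LETTER_TO_INDEX: dict[str, int] = {a: i

                                   for i, a in enumerate(ALPHABET)}

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _a, _i in LETTER_TO_INDEX.items():
    _LOOKUP[ord(_a)] = _i


def indices_of(row: str) -> np.ndarray:
    """Map an aligned row to integer letter indices (gap = 20).

    Raises ``ValueError`` naming the first offending position if a character
    is outside the alphabet.
    """
    codes = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    idx = _LOOKUP[codes]
    if (idx < 0).any():
        pos = int(np.argmax(idx < 0))
        raise ValueError(
            f"letter {row[pos]!r} at position {pos} is not in alphabet {ALPHABET!r}"
        )
    return idx.astype(np.int64)
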