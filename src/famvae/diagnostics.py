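"""Information-theoretic model-fidelity diagnostics.

Per-column letter frequencies (gap counted as a 21st letter, raw counts, no
pseudocounts), site entropies H_j, the full pairwise mutual-information
matrix I_{j,k}, and the agreement statistics used to judge a generative
model: squared Pearson correlation of pooled frequencies and of off-diagonal
MI between training data and model samples, and the correlation between
Hamming distance to the wildtype and Euclidean distance between latent means.

All entropies/MI are in nats by default (``base`` switches to bits).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import Alignment
from .encoding import encode_alignment, one_hot_encode
from .sampling import hamming_distance
from .vae import SequenceVAE

__all__ = [
    "FidelityReport",
    "column_frequencies",
    "column_entropy",
    "joint_entropy",
    "mutual_information",
    "mutual_information_pair",
    "fidelity_r2",
    "hamming_latent_correlation",
    "plot_mi_heatmap",
]


@dataclass
class FidelityReport:
    freq_r2: float | None = None
    mi_r2: float | None = None
    hamming_latent_r2_all: float | None = None
    hamming_latent_r2_closest5: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _rows_or_alignment(data: Alignment | np.ndarray | list[str]) -> np.ndarray:
    """Accept an Alignment, a list of rows, or a pre-encoded (N, L, A) stack."""
    if isinstance(data, Alignment):
        return encode_alignment(data)
    if isinstance(data, np.ndarray):
        return data
    return np.stack([one_hot_encode(r) for r in data])


def column_frequencies(data: Alignment | np.ndarray | list[str]) -> np.ndarray:
    """(L, 21) table of empirical letter frequencies n_j^a / N per column."""
    x = _rows_or_alignment(data)
    if x.shape[0] < 1:
        raise ValueError("need at least one sequence")
    # accumulate in float64: one-hot sums are exact integers
    return x.mean(axis=0, dtype=np.float64)


def column_entropy(freq: np.ndarray, base: str = "nats") -> np.ndarray:
    """Shannon entropy -sum p log p per row of a frequency table (0 log 0 = 0)."""
    p = np.atleast_2d(np.asarray(freq, dtype=np.float64))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1)
    if base == "bits":
        h = h / math.log(2)
    elif base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return h if np.asarray(freq).ndim > 1 else h[0]


def _joint_counts(x: np.ndarray) -> np.ndarray:
    """(L, A, L, A) pair-count tensor via one Gram matrix."""
    N, L, A = x.shape
    flat = x.reshape(N, L * A)
    gram = flat.T.astype(np.float32) @ flat.astype(np.float32)
    return gram.reshape(L, A, L, A).astype(np.float64)


def joint_entropy(data: Alignment | np.ndarray | list[str],
                  base: str = "nats") -> np.ndarray:
    """(L, L) matrix of joint column entropies H_{j,k}; diagonal is H_j."""
    x = _rows_or_alignment(data)
    counts = _joint_counts(x)
    p = counts / x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=(1, 3))
    if base == "bits":
        h = h / math.log(2)
    return h


def mutual_information(data: Alignment | np.ndarray | list[str],
                       base: str = "nats") -> np.ndarray:
    """(L, L) mutual-information matrix from raw pair counts.

    Off-diagonal entries are I_{j,k} = sum_ab p_ab log(p_ab / (p_a p_b));
    the diagonal carries the site entropy H_j (the self-information).
    """
    x = _rows_or_alignment(data)
    if x.shape[0] < 2:
        raise ValueError("need at least two sequences")
    N, L, A = x.shape
    counts = _joint_counts(x)
    p_joint = counts / N
    freq = column_frequencies(x)  # (L, A)
    outer = freq[:, :, None, None] * freq[None, None, :, :]  # p_a * p_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_joint > 0, p_joint / np.where(outer > 0, outer, 1.0), 1.0)
        terms = np.where(p_joint > 0, p_joint * np.log(ratio), 0.0)
    mi = terms.transpose(0, 2, 1, 3).reshape(L, L, A * A).sum(axis=-1)
    np.fill_diagonal(mi, column_entropy(freq))
    mi = 0.5 * (mi + mi.T)  # enforce exact symmetry
    if base == "bits":
        mi = mi / math.log(2)
    return mi


def mutual_information_pair(rows: list[str], j: int, k: int) -> float:
    """I_{j,k} for one column pair, by direct pair counting (nats).

    Convenience path for spot checks; the matrix routine is equivalent.
    """
    n = len(rows)
    pair_counts: dict[tuple[str, str], int] = {}
    a_counts: dict[str, int] = {}
    b_counts: dict[str, int] = {}
    for r in rows:
        pair_counts[(r[j], r[k])] = pair_counts.get((r[j], r[k]), 0) + 1
        a_counts[r[j]] = a_counts.get(r[j], 0) + 1
        b_counts[r[k]] = b_counts.get(r[k], 0) + 1
    mi = 0.0
    for (a, b), c in pair_counts.items():
        p_ab = c / n
        mi += p_ab * math.log(p_ab / ((a_counts[a] / n) * (b_counts[b] / n)))
    return mi


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation; None when either vector is constant."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def fidelity_r2(
    train: Alignment | np.ndarray | list[str],
    samples: Alignment | np.ndarray | list[str],
) -> FidelityReport:
    """Frequency and MI agreement between training data and model samples.

    ``freq_r2`` pools all L x 21 per-position letter frequencies; ``mi_r2``
    pools the upper-triangle (off-diagonal) mutual-information values.
    """
    xt = _rows_or_alignment(train)
    xs = _rows_or_alignment(samples)
    if xt.shape[1:] != xs.shape[1:]:
        raise ValueError("train and samples must share width and alphabet")
    ft = column_frequencies(xt)
    fs = column_frequencies(xs)
    iu = np.triu_indices(xt.shape[1], k=1)
    mt = mutual_information(xt)[iu]
    ms = mutual_information(xs)[iu]
    return FidelityReport(
        freq_r2=_pearson_r2(ft, fs),
        mi_r2=_pearson_r2(mt, ms),
    )


def hamming_latent_correlation(
    model: SequenceVAE,
    aln: Alignment,
    target_id: str | None = None,
    closest_fraction: float = 0.05,
) -> tuple[float | None, float | None]:
    """R^2 between Hamming distance to the wildtype and latent-mean distance.

    Returns the statistic over all sequences and over the ceil(fraction * N)
    sequences closest to the wildtype by Hamming distance (ties broken by
    input order); either is None if degenerate (constant distances or a
    subset smaller than 3).
    """
    target_id = target_id or aln.target_id
    target_row = aln.row(target_id)
    x = encode_alignment(aln)
    mus = []
    for start in range(0, x.shape[0], 256):
        mus.append(model.encode(x[start:start + 256], train=False).mu)
    mu = np.concatenate(mus, axis=0)
    mu_t = mu[aln.ids.index(target_id)]
    ham = np.array([hamming_distance(r, target_row) for r in aln.rows], dtype=float)
    lat = np.linalg.norm(mu - mu_t, axis=1)

    r2_all = _pearson_r2(ham, lat)
    n_sub = math.ceil(closest_fraction * aln.depth)
    order = np.argsort(ham, kind="stable")[:n_sub]
    r2_sub = _pearson_r2(ham[order], lat[order]) if n_sub >= 3 else None
    return r2_all, r2_sub


def frequency_table_to_tsv(freq: np.ndarray, path: str | Path,
                           alphabet: str | None = None) -> None:
    from .alphabet import ALPHABET

    cols = list(alphabet or ALPHABET)
    pd.DataFrame(freq, columns=cols).to_csv(path, sep="\t", index_label="column")


def plot_mi_heatmap(mi: np.ndarray, path: str | Path,
                    title: str = "mutual information (nats)") -> None:
    """Save an MI matrix heatmap (off-diagonal values only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = mi.copy()
    np.fill_diagonal(shown, 0.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(shown, cmap="viridis")
    ax.set_xlabel("alignment column")
    ax.set_ylabel("alignment column")
    ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
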