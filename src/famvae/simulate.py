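"""Synthetic protein families with known statistical structure.

Every downstream module is testable without any database download: the
generator emits an alignment with (i) designed per-column letter profiles,
(ii) designed coupled column pairs whose joint distribution — and therefore
exact mutual information — is known in closed form, (iii) a gradient of
identity to a designated target sequence (each sequence mutates away from the
target at its own rate), and (iv) sprinkled gaps. A companion generator
simulates replicate phenotype measurements as a linear function of binary
mutation indicators plus Gaussian noise, for exercising the mutation-effect
regression with known coefficients.

Gaps are never inserted at designed coupled columns, so the designed joint
distribution (and its exact MI oracle) is preserved in the emitted data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, AMINO_ACIDS, GAP, LETTER_TO_INDEX
from .curation import Alignment

__all__ = [
    "FamilyConfig",
    "PhenotypeConfig",
    "generate_family",
    "ground_truth",
    "generate_phenotypes",
    "synthetic_regression_dataset",
]

JointDist = dict[tuple[str, str], float]


@dataclass
class FamilyConfig:
    """Generative description of a synthetic family.

    site_profiles
        (L, 20) row-normalized replacement distributions over amino acids; a
        mutated position draws its letter from its column's profile.
    coupled_pairs
        (j, k, joint) triples; those two columns are always drawn jointly
        from ``joint`` (letter-pair -> probability), independent of the
        per-sequence mutation rate, so their mutual information is designed.
    identity_range
        (min, max) fraction identity to the target; each sequence draws a
        mutation rate uniformly from (1 - max, 1 - min).
    gap_rate
        Per-cell gap probability (skipped at coupled columns and in the
        target row).
    """

    L: int
    N: int
    target: str
    site_profiles: np.ndarray
    coupled_pairs: list[tuple[int, int, JointDist]] = field(default_factory=list)
    identity_range: tuple[float, float] = (0.4, 1.0)
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.target) != self.L:
            raise ValueError("target length must equal L")
        if self.site_profiles.shape != (self.L, len(AMINO_ACIDS)):
            raise ValueError("site_profiles must be (L, 20)")
        if not np.allclose(self.site_profiles.sum(axis=1), 1.0):
            raise ValueError("site_profiles rows must sum to 1")
        used: set[int] = set()
        for j, k, joint in self.coupled_pairs:
            if j == k or not (0 <= j < self.L and 0 <= k < self.L):
                raise ValueError(f"bad coupled pair ({j}, {k})")
            if used & {j, k}:
                raise ValueError("coupled pairs must be disjoint")
            used |= {j, k}
            if not np.isclose(sum(joint.values()), 1.0):
                raise ValueError(f"joint distribution of ({j}, {k}) must sum to 1")
        lo, hi = self.identity_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("identity_range must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must lie in [0, 1)")

    @property
    def coupled_columns(self) -> list[int]:
        return sorted({c for j, k, _ in self.coupled_pairs for c in (j, k)})

    @classmethod
    def random(
        cls,
        L: int = 64,
        N: int = 2000,
        seed: int = 0,
        n_coupled: int = 1,
        gap_rate: float = 0.02,
        identity_range: tuple[float, float] = (0.4, 1.0),
    ) -> "FamilyConfig":
        """A realistic default family: sparse per-column profiles in which the
        target letter stays the plurality choice, plus ``n_coupled`` designed
        two-state coupled pairs of one bit (log 2 nats) each."""
        rng = np.random.default_rng(seed)
        aa = len(AMINO_ACIDS)
        target_idx = rng.integers(0, aa, size=L)
        profiles = np.zeros((L, aa))
        for j in range(L):
            n_alt = int(rng.integers(2, 6))
            alts = rng.choice(
                [a for a in range(aa) if a != target_idx[j]],
                size=n_alt, replace=False,
            )
            w_target = rng.uniform(0.3, 0.6)
            w_alts = rng.dirichlet(np.ones(n_alt)) * (1.0 - w_target)
            profiles[j, target_idx[j]] = w_target
            profiles[j, alts] = w_alts
        target = "".join(AMINO_ACIDS[i] for i in target_idx)

        cols = rng.choice(L, size=2 * n_coupled, replace=False)
        pairs: list[tuple[int, int, JointDist]] = []
        t = list(target)
        for m in range(n_coupled):
            j, k = int(cols[2 * m]), int(cols[2 * m + 1])
            (a1, b1), (a2, b2) = rng.choice(list(AMINO_ACIDS), size=(2, 2))
            while a2 == a1 or b2 == b1:
                (a2, b2) = rng.choice(list(AMINO_ACIDS), size=2)
            pairs.append((j, k, {(a1, b1): 0.5, (a2, b2): 0.5}))
            t[j], t[k] = a1, b1  # keep the target consistent with state 1
        return cls(
            L=L, N=N, target="".join(t), site_profiles=profiles,
            coupled_pairs=pairs, identity_range=identity_range,
            gap_rate=gap_rate, seed=seed,
        )


def generate_family(cfg: FamilyConfig) -> Alignment:
    """Draw the family; the target is included verbatim as the first record."""
    rng = np.random.default_rng(cfg.seed)
    aa = len(AMINO_ACIDS)
    L, N = cfg.L, cfg.N
    n_draw = N - 1
    target_idx = np.array([LETTER_TO_INDEX[c] for c in cfg.target])

    lo, hi = cfg.identity_range
    rates = rng.uniform(1.0 - hi, 1.0 - lo, size=n_draw)
    mutate = rng.random((n_draw, L)) < rates[:, None]
    seqs = np.tile(target_idx, (n_draw, 1))
    for j in range(L):
        draws = rng.choice(aa, size=n_draw, p=cfg.site_profiles[j])
        seqs[mutate[:, j], j] = draws[mutate[:, j]]

    for j, k, joint in cfg.coupled_pairs:
        states = list(joint)
        probs = np.array([joint[s] for s in states])
        pick = rng.choice(len(states), size=n_draw, p=probs)
        seqs[:, j] = [LETTER_TO_INDEX[states[s][0]] for s in pick]
        seqs[:, k] = [LETTER_TO_INDEX[states[s][1]] for s in pick]

    if cfg.gap_rate > 0:
        gaps = rng.random((n_draw, L)) < cfg.gap_rate
        gaps[:, cfg.coupled_columns] = False
        seqs[gaps] = LETTER_TO_INDEX[GAP]

    rows = [cfg.target] + ["".join(ALPHABET[i] for i in row) for row in seqs]
    ids = ["target"] + [f"seq{i + 1:05d}" for i in range(n_draw)]
    desc = ["synthetic target"] + ["synthetic family member"] * n_draw
    return Alignment(ids=ids, rows=rows, target_id="target", descriptions=desc)


def ground_truth(cfg: FamilyConfig) -> tuple[np.ndarray, dict[tuple[int, int], float]]:
    """Exact expected column frequencies and exact MI per designed pair.

    Frequencies are over the full 21-letter alphabet (gap included) for the
    non-target population; MI is the closed-form double sum over each
    designed joint distribution (nats).
    """
    lo, hi = cfg.identity_range
    mean_rate = ((1.0 - hi) + (1.0 - lo)) / 2.0
    A = len(ALPHABET)
    freqs = np.zeros((cfg.L, A))
    coupled = {c for c in cfg.coupled_columns}
    for j in range(cfg.L):
        if j in coupled:
            continue
        p = mean_rate * cfg.site_profiles[j].copy()
        p[[LETTER_TO_INDEX[cfg.target[j]]]] += 1.0 - mean_rate
        freqs[j, : len(AMINO_ACIDS)] = p * (1.0 - cfg.gap_rate)
        freqs[j, A - 1] = cfg.gap_rate
    mi: dict[tuple[int, int], float] = {}
    for j, k, joint in cfg.coupled_pairs:
        pa: dict[str, float] = {}
        pb: dict[str, float] = {}
        for (a, b), p in joint.items():
            pa[a] = pa.get(a, 0.0) + p
            pb[b] = pb.get(b, 0.0) + p
            freqs[j, LETTER_TO_INDEX[a]] += p
            freqs[k, LETTER_TO_INDEX[b]] += p
        mi[(j, k)] = sum(
            p * np.log(p / (pa[a] * pb[b]))
            for (a, b), p in joint.items()
            if p > 0
        )
    return freqs, mi


@dataclass
class PhenotypeConfig:
    """Linear phenotype model: y = sum(beta[mutation]) + library effect + noise."""

    beta_activity: dict[str, float]
    beta_tm: dict[str, float]
    noise_sd: tuple[float, float] = (0.5, 0.5)
    library_effect: tuple[float, float] = (0.0, 0.0)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_phenotypes(
    mutations_per_variant: Mapping[str, Sequence[str]],
    pcfg: PhenotypeConfig,
    library_labels: Mapping[str, int],
) -> pd.DataFrame:
    """Replicate activity / melting-temperature measurements per variant.

    Columns: variant_id, library, activity_rep1..R, tm_rep1..R. Seeded and
    reproducible; unknown mutations (absent from both beta maps) contribute 0.
    """
    rng = np.random.default_rng(pcfg.seed)
    rows = []
    for vid, muts in mutations_per_variant.items():
        lib = int(library_labels[vid])
        base_act = sum(pcfg.beta_activity.get(m, 0.0) for m in muts)
        base_tm = sum(pcfg.beta_tm.get(m, 0.0) for m in muts)
        base_act += pcfg.library_effect[0] * lib
        base_tm += pcfg.library_effect[1] * lib
        row: dict[str, object] = {"variant_id": vid, "library": lib}
        for r in range(1, pcfg.n_replicates + 1):
            row[f"activity_rep{r}"] = base_act + rng.normal(0, pcfg.noise_sd[0])
            row[f"tm_rep{r}"] = base_tm + rng.normal(0, pcfg.noise_sd[1])
        rows.append(row)
    return pd.DataFrame(rows)


def synthetic_regression_dataset(
    n_variants: int = 180,
    n_mutations: int = 47,
    seed: int = 0,
    noise_to_signal: float = 0.5,
    library_effect: tuple[float, float] = (-0.5, -0.5),
) -> tuple[dict[str, list[str]], dict[str, int], PhenotypeConfig]:
    """A regression test-bed with known ground-truth coefficients.

    Builds a mutation universe of ``n_mutations`` names (mix of substitutions
    and deletions across a 322-residue coordinate frame), assigns each
    variant 5-16 of them at random, splits variants evenly between the two
    libraries, and sets the replicate noise standard deviation to
    ``noise_to_signal`` times the standard deviation of the noiseless signal.
    Returns (mutations per variant, library labels, phenotype config).
    """
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(2, 322), size=n_mutations, replace=False)
    universe: list[str] = []
    for i, pos in enumerate(sorted(positions)):
        src, dst = rng.choice(list(AMINO_ACIDS), size=2)
        if i % 8 == 7:
            universe.append(f"Δ{src}{pos}")
        else:
            while dst == src:
                dst = rng.choice(list(AMINO_ACIDS))
            universe.append(f"{src}{pos}{dst}")
    beta_act = {m: float(rng.normal(0, 1.0)) for m in universe}
    beta_tm = {m: float(rng.normal(0, 1.0)) for m in universe}

    mutations: dict[str, list[str]] = {}
    labels: dict[str, int] = {}
    for i in range(n_variants):
        vid = f"v{i + 1:04d}"
        k = int(rng.integers(5, 17))
        mutations[vid] = list(rng.choice(universe, size=k, replace=False))
        labels[vid] = int(i >= n_variants // 2)

    signal_act = np.array(
        [sum(beta_act[m] for m in muts) + library_effect[0] * labels[v]
         for v, muts in mutations.items()]
    )
    signal_tm = np.array(
        [sum(beta_tm[m] for m in muts) + library_effect[1] * labels[v]
         for v, muts in mutations.items()]
    )
    pcfg = PhenotypeConfig(
        beta_activity=beta_act,
        beta_tm=beta_tm,
        noise_sd=(
            noise_to_signal * float(np.std(signal_act, ddof=1)),
            noise_to_signal * float(np.std(signal_tm, ddof=1)),
        ),
        library_effect=library_effect,
        seed=seed + 1,
    )
    return mutations, labels, pcfg
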