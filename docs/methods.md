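# Methods

This note documents the models and procedures implemented in `famvae`, the
choices made where the design was genuinely open, and what the synthetic
test-bed does and does not establish about behavior on real alignments.

## Alignment curation

A sequence's **gappiness** is

    s_i = Σ_{j ∈ G_i} f_j,    f_j = N_gap(j)/N  if  N_gap(j)/N > w,  else 0,

where G_i is the set of columns at which sequence i is gapped, N is the
alignment depth, and w ∈ [0, 1] a column-level threshold. Sequences with
s_i above a cutoff are removed; defaults are w = 0.9, cutoff 10, minimum
ungapped length 290, and an optional description keyword (default off; the
preset for ornithine transcarbamylase work is the keyword "Ornithine" with
case-sensitive substring matching, configurable because public record
descriptions are not normalized).

Decisions:

- The inequality on the column gap fraction is **strict**: a column at
  exactly fraction w contributes nothing.
- Gap fractions are computed **once** on the input alignment; filtering does
  not trigger re-scoring (a single scoring pass, so the removal set does not
  depend on removal order).
- Filter order is gappy → short → keyword. The final set is order-invariant;
  only the per-reason tallies depend on order.
- Column indices in reports are 0-based; residue coordinates in mutation
  names are 1-based wildtype coordinates (A135T, ΔK70).
- On reading, `.` becomes `-` and lowercase is uppercased. Ambiguity codes
  (B, J, X, Z, U, O) are rejected by default or mapped to the gap letter
  with `ambiguous="gap"`.

After filtering, columns where the target row is gapped are sliced away, so
model coordinates are wildtype residue coordinates and the target row
contains no gaps. Slicing is idempotent.

## Encoding and weighting

The alphabet is the fixed string `ACDEFGHIKLMNPQRSTVWY-` (20 amino acids,
then gap), serialized with every checkpoint. Sequences are (L × 21) one-hot
matrices; argmax over the alphabet dimension inverts the encoding.

Training weights are identity(sequence, wildtype)^2.25. Sequence identity is
the fraction of identical columns over the full alignment width, with
gap-gap columns counting as matches and gap-letter as mismatches — the
simplest symmetric convention; it is documented here because identity enters
only through the weights, where a constant-factor change in convention is
mostly absorbed by the exponent. Weights enter training **only through the
batch sampler** (weighted sampling with replacement), never through loss
reweighting. The train/test split is seeded, disjoint and exhaustive
(default 90/10); the wildtype is forced into the training split because the
sampling stage must encode it.

## The variational autoencoder

Architecture (defaults; all configurable):

| piece | choice |
|---|---|
| input | (L, 21) one-hot, padded on the right to L' = ⌈L/8⌉·8 with gap columns |
| encoder | 3 × [3×3 conv (same padding) → batch norm → ELU → 2× max pool, length only] |
| encoder filters | 128, 96, 64 |
| latent heads | flatten → two affine maps → μ, log σ² (latent dim 64) |
| decoder | affine map from z → 3 × [3×3 conv → batch norm → ELU → 2× nearest-neighbor upsample, length only] → 3×3 conv to 1 channel |
| decoder filters | 64, 96, 128 |
| output | crop to L, softmax over the alphabet dimension |
| init | Kaiming normal, seeded |
| optimizer | Adam, learning rate 1e-3 (toy runs below use 3e-3) |

The loss is the negative evidence lower bound: mean per-sequence
cross-entropy (sum over positions, in nats) plus β times the closed-form
Gaussian KL divergence 0.5·Σ_d(e^{log σ²} + μ² − 1 − log σ²). β rises
linearly from 0 (first epoch) to 1 (last epoch) to avoid posterior collapse.
Probabilities are clamped at 1e-8 before logs. Test loss is evaluated
deterministically at the posterior mean and recorded both at the annealed β
and at β = 1; the β = 1 value is the comparable model-selection number.

Numerical/design notes:

- Convolution geometry (kernel 3×3, same padding, pooling/upsampling on the
  length axis only, the affine latent heads) is a declared default, chosen
  as the simplest geometry consistent with "three blocks, pool 2× in
  length"; it is not the only reasonable one.
- Length padding uses the gap letter (the least informative letter); the
  padded columns are cropped before the loss, so they never contribute to
  the objective.
- The variance is parameterized as log σ² for stability; σ is reported as
  exp(log σ²/2).
- Batch normalization follows each convolution (toggleable). Its running
  statistics are part of the checkpoint. On CPU-scale runs batch norm
  measurably improves both convergence and the calibration of prior-sample
  decoding.
- Training is fully deterministic given the seed (pure numpy; no
  backend nondeterminism).
- A NaN loss aborts with a diagnostic rather than continuing.
- Early stopping is off by default (fixed epoch count); optional patience
  on the β = 1 test loss.

The whole network, including backprop and Adam, is implemented in numpy
(`famvae/_layers.py`). The backward pass is verified end-to-end against
central finite differences in float64; note that exact one-hot inputs can
park max pooling on exact ties where the loss is non-differentiable, so the
gradient check uses strictly continuous inputs.

## Variant sampling

The wildtype is encoded once to (μ, σ²). At each scale s in an increasing
schedule, z ~ N(μ, s·σ²) is drawn and argmax-decoded; scale 0 decodes the
posterior mean (the maximum-a-posteriori sequence). Decoded sequences equal
to the wildtype are skipped; those above the mutation cap (default 16, ~5%
of a 322-residue protein) are dropped; duplicates keep their first
occurrence's scale. By default the sweep stops at the first scale that
produces any over-cap sequence ("until we reach the cap"); a
filter-and-continue mode is available. The schedule default is geometric
(0, 0.25, 0.5, 1, 2, 4, 8, 16) with 100 samples per scale — the schedule is
a knob, not a claim. `scale_sigma=True` multiplies σ instead of σ²; only
the meaning of the schedule values changes.

Decoded gap letters are kept as deletions (Δ-prefixed), not resampled:
deletions are real design moves in this family. Mutation names are 1-based
in wildtype coordinates, so applying the mutation list to the wildtype
reconstructs the variant row exactly (a tested round trip).

Model samples for *distribution diagnostics* are drawn differently: z from
the standard-normal prior and letters sampled from the decoder's categorical
distributions (`sample_sequences(..., decode="sample")`). Argmax decoding is
a mode-seeking readout appropriate for picking variants; distribution
comparisons need actual samples from p(x|z), otherwise per-column
frequencies are biased toward each column's modal letter.

## Fidelity diagnostics

Frequencies are raw counts over the 21-letter alphabet (gap included), with
no pseudocounts or small-sample corrections. Entropies and mutual
information are in nats by default (`base="bits"` available). The MI matrix
is computed from pair counts via one Gram-matrix product; the identity
I = H_j + H_k − H_{j,k} and a direct per-pair double sum serve as
cross-checks in the tests (agreement to 1e-10). The diagonal carries H_j.

R² values are squared Pearson correlations of the paired scatter (pooled
frequencies; upper-triangle MI), not regression R². Degenerate scatters
(zero variance) report as missing rather than 0 or 1. The Hamming-vs-latent
correlation uses Euclidean distance between posterior means (deterministic);
the "closest 5%" subset is the ⌈0.05·N⌉ sequences with smallest Hamming
distance to the wildtype, ties broken by input order.

## Consensus design

The consensus letter of a column is the most frequent non-gap letter, ties
broken by alphabet order (deterministic and documented; a column that is
majority-gap still elects its most frequent amino acid, and an all-gap
column is an error). The k consensus substitutions relative to the wildtype
define a 2^k combinatorial library (including the unmodified wildtype); the
library can be enumerated (guarded at k ≤ 25) or sampled uniformly without
replacement at the amino-acid level. Nucleotide-level library construction
(degenerate codons) is out of scope, so codon-induced biases and the extra
amino acids they admit are not modeled.

## Mutation-effect regression

Rows are assayed variants; columns are binary indicators for every mutation
observed in at least one variant (substitutions and deletions share one
namespace), plus a "library" column (0 = model-sampled library, 1 =
consensus library) capturing assay-group offsets. Replicates are averaged
per variant, then standardized using the sample standard deviation (n−1).
The ridge solution is closed-form on the centered design with an unpenalized
intercept — the intercept keeps the model well-posed with a group covariate
even though the idealized formulation omits it. λ defaults to 1.0 on
standardized responses; exact leave-one-out cross-validation over a log grid
(SVD/hat-matrix identity, no refitting) is available and used in the
recovery analyses. Multi-residue deletions are encoded as their constituent
single-position deletion columns co-occurring.

Quadrant labels classify each mutation by the signs of its activity and T_m
coefficients ("++", "+-", "-+", "--", exact zeros "neutral"), sorted by
Euclidean coefficient magnitude.

## The synthetic test-bed

`famvae.simulate` generates families with known structure so every stage has
an exact oracle:

- **Site profiles**: per column, a sparse replacement distribution over the
  20 amino acids in which the target letter keeps weight 0.3-0.6 and 2-5
  alternatives share the rest — emulating site-wise conservation.
- **Identity gradient**: each sequence draws a mutation rate uniformly from
  (1 − id_max, 1 − id_min), default identity range 40-100% to the target,
  emulating a family whose members span distant homologs to near-wildtype
  relatives.
- **Designed couplings**: chosen column pairs are always drawn jointly from
  an explicit joint distribution (default two equiprobable letter pairs →
  exactly log 2 nats of mutual information). Explicit joints rather than a
  Potts model: the MI oracle is closed-form and sampling is cheap.
- **Gaps** at a per-cell rate (default 2%), never at coupled columns so the
  designed MI stays exact.
- **Phenotypes**: y = Σ β(mutation) + library offset + Gaussian noise per
  replicate, two responses, three replicates — exactly the linear model the
  regression stage assumes.

Finite-sample MI bias is deliberately not corrected (matching the raw-count
convention); test tolerances absorb it.

What the synthetic family does **not** emulate: phylogenetic correlation
between sequences (draws are independent given the target), higher-order
epistasis beyond pairwise joints, realistic gap blocks (indel runs), and
database annotation noise. Passing the end-to-end checks therefore shows the
machinery is correct and well-calibrated at this scale — not that a given
real family is modeled well; for real data the fidelity diagnostics are the
arbiter.

## Study-scale configuration

The end-to-end checks and `scripts/acceptance.py` train on the default
synthetic family (L = 64, N = 2000, one coupled pair, 2% gaps, seed-fixed)
for 20 epochs at batch size 128 with a reduced architecture (filters
32/24/16, latent 16, learning rate 3e-3) sized so the whole pipeline runs in
minutes on one CPU. The full-scale defaults (L = 322, filters 128/96/64,
latent 64, 30 epochs, learning rate 1e-3) are the library defaults for real
alignments. Under the toy conditions the trained model reaches per-column
frequency R² ≥ 0.9 against its training data, and the designed coupled
pair's sample MI exceeds the median MI of non-coupled pairs.

## Known limitations

- An "epoch" is ⌈n_train/batch⌉ weighted draws with replacement, so a small
  family sees few gradient steps; the toy configuration compensates with a
  higher learning rate.
- Prior samples from a batch-normalized decoder are evaluated with running
  statistics; their calibration is diagnosed, not guaranteed. At the toy
  scale the frequency R² (a correlation, hence scale-free) can be high while
  the frequency scatter's slope is well below 1 — the model ranks site
  preferences correctly but its prior samples are more diverse than the
  training data. The acceptance script reports this slope alongside the R²
  so the calibration is visible, not hidden.
- The regression assumes additive mutation effects; epistasis terms are out
  of scope.
- Uniform sampling of the consensus library stands in for the wet-lab
  transform-and-pick-clones procedure; clone-picking biases are not modeled.
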