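# Methods

## Pipeline overview

The package classifies nucleotide sequences into six mutation classes
(normal, EGFR deletion, EGFR substitution, KRAS substitution, TP53
deletion, TP53 substitution) in three stages: Voss indicator encoding of
the sequence into a 4 × N binary image, extraction of a fixed-length image
descriptor (HOG or LBP), and supervised classification with multilayer
perceptrons or one-against-all kernel SVMs, each available in single and
ensemble form. Class targets are 6-element one-hot vectors for the
networks and the integers 1–6 for the SVMs, in the fixed order listed
above; ties anywhere in the pipeline resolve toward the lowest class index.

## Voss encoding

Each base maps to one of four indicator rows (A, C, G, T, top to bottom);
entry (r, k) is 1 iff base k is the row's nucleotide, so every column sums
to exactly 1 and decoding is exact. Lowercase input is upper-cased before
validation; IUPAC ambiguity codes are rejected rather than coerced, since
the mapping is defined only on A/C/G/T. Mutation coordinates are 0-based
offsets; deletions remove one contiguous run, and a substitution equal to
the reference base is rejected as a no-op.

## HOG descriptor

* **Gradients.** Correlation with the centered mask [−1, 0, 1] along both
  axes, with replicate-edge padding so the derivative images keep the
  input's shape and every pixel can vote. Magnitude is the Euclidean norm;
  orientation is the two-argument arctangent in degrees folded into
  [0°, 180°) (unsigned). Pixels with zero gradient get θ = 0 and carry no
  vote, avoiding the undefined ratio at I_x = 0.
* **Binning.** 9 channels of 20° (180/20), half-open bins [lo, hi); a
  folded orientation of exactly 180° wraps to bin 0. Each pixel assigns
  its full magnitude to one bin (no interpolation), so a cell histogram's
  mass equals the summed gradient magnitude of the cell — a conservation
  property the tests verify.
* **Geometry.** The full 4-row height is a single cell row. The width is
  partitioned into 5 equal-width cells (any remainder goes to the last
  cell), each cell is halved, and the 9 blocks are the consecutive pairs
  of the resulting 10 half-spans — adjacent blocks overlap by half a
  block, and 2·5 − 1 = 9 blocks × 9 bins gives the 81-length descriptor
  for every sequence of length ≥ 10. This length invariance across
  variable-length genes is the property the block layout is chosen to
  deliver.
* **Normalization.** Per block, L2 by default: v/√(‖v‖₂² + e²) with
  e = 10⁻⁵ (the value does not materially influence the result; any
  positive e bounds the normalized sub-norm by 1). L1 and L1-sqrt schemes
  are provided.

A structural note: a homopolymer's image has constant rows, so its
horizontal derivative vanishes everywhere, but the boundaries between the
four different indicator rows still produce vertical gradients — its
descriptor therefore concentrates all mass in the 90° bin rather than
being zero.

## LBP descriptor

Basic 8-neighbor, radius-1 LBP: each interior pixel's code sets bit i when
neighbor i (clockwise from the top-left, weights 2⁰…2⁷) is ≥ the center.
The descriptor is the raw 256-bin code histogram (summing to
(rows−2)·(cols−2)); a normalized variant is available. No uniform-pattern
or rotation-invariant mappings are applied. Raw counts deliberately retain
sequence-length information, which is informative for separating deletion
classes from substitution classes.

## Network classifier and SCG training

Architecture: input width = descriptor length (81 HOG / 256 LBP), two
hidden layers of equal width H, six tanh outputs. The sweep protocol
varies H from 10 to 100 in steps of 10; the sweep harness trains the ten
networks and reports MSE and accuracy on both the full data and the test
split, labeling the evaluation set explicitly. Targets are {0,1} one-hot
vectors trained directly under tanh outputs and decoded by argmax.

Training minimizes the MSE (mean over samples and output units) with
Møller's scaled conjugate gradient using the published defaults
(σ₀ = 5·10⁻⁵, initial λ = 5·10⁻⁷); each successful weight update counts as
one epoch, capped at 500 by default. Weights start from a seeded uniform
range ±1/√fan-in. Early stopping records per-epoch train/validation MSE
and returns the weights of the epoch with minimum validation MSE.
Data splits are stratified 70/15/15 (train/validation/test) with exact
global sizes via largest-remainder rounding; classes with fewer samples
than splits trigger a warning and degrade gracefully to the nearest
feasible allocation. Features are z-scored on the training split by
default — LBP raw counts are O(10³) and would otherwise saturate tanh.

**Bagging ensemble.** n_base networks (default 50) are trained on
equal-size bootstrap resamples; each member uses its out-of-bag samples as
its early-stopping validation set and its selection benchmark, so no
training data is wasted on a second carve-out. Members with OOB accuracy
≥ 0.9475 ("approximately 95% and above") are kept, topped up or cut down
to exactly n_selected (default 12) by accuracy rank so small corpora still
yield a full ensemble. Prediction is a per-sample plurality vote,
invariant to member order, ties to the lowest class index.

## SVM classifier

One binary soft-margin machine per class (class versus rest), prediction
by the largest decision value. Kernels: linear; quadratic (polynomial
degree 2); polynomial degree 3 (the common default, distinct from the
separately listed quadratic kernel); RBF; and the sigmoid "MLP" kernel
tanh(γ⟨x, x′⟩ + c) with γ = 1/d and c = −1. The regularization constant is
C = 1 by default and exposed in configuration. The binary machines are
scikit-learn SVCs behind the one-against-all surface.

Evaluation uses 20 repeated seeded stratified 80/20 holdouts — reporting mean
accuracy and mean MSE over rounds. SVM MSE is computed from one-hot-coded
predictions against one-hot targets, the same metric as the networks, so
the summary grid is comparable across model families. The bucket-of-models
ensemble trains n_models seeded machines on re-split data and keeps the
single best by holdout accuracy (first best on ties, deterministically).

## Evaluation

Confusion matrices use rows = true class, columns = predicted class, fixed
class order; accuracy is 100·trace/total, reported to one decimal place.
The summary grid holds one row per classifier × descriptor combination in
the canonical eight-row order. Reports embed seeds and configuration so
any row is re-derivable — an artifact guarantee of this package.
`member_table_summary` reproduces the total/average arithmetic of
per-member ensemble tables.

## Synthetic corpus

The generator emulates the structure of the mutation corpus the pipeline
is designed for: three uniform-random reference genes of 3633 (EGFR-like),
567 (KRAS-like), and 1182 (TP53-like) bases, and per-class sample counts
at the emulated acquired-count proportions 2640 : 975 : 2472 : 42 : 277.
Defaults use scale 0.047 — 124/46/116/2/13 mutation samples (301) plus 21
normal samples (7 copies per gene), 322 in all, a desk-scale corpus that
trains in seconds. Each mutated sample is a full-length gene variant
carrying a single event: a substitution to a uniformly chosen different
base at a uniform position, or a contiguous deletion of 3–24 bases
(spanning typical in-frame deletion sizes for these genes; the range is
configurable since no distribution is prescribed). The normal class pools
unmutated copies of all three genes under one label. A `unique_only` mode
deduplicates mutant sequences with an explicit capacity check. The corpus
is a pure function of its configuration, including the seed.

What the generator does *not* emulate: mutation hotspots, codon and
reading-frame structure, germline variation, real base composition, or the
database's construction of per-sample sequences from mutation records
(unknowable from its description; full-length single-event variants are
the simplest consistent construction, and fragment-centered modes are left
unimplemented). Passing tests on this corpus therefore demonstrate the
pipeline's mechanics and the separability of the emulated class structure,
not clinical performance on real genomes; accuracy figures obtained on
real mutation databases cannot be reproduced from synthetic data.

## Desk-scale study settings

The synthetic-corpus experiments (acceptance script and acceptance tests)
use hidden width 30, 200 epochs, 15 bagged networks with 5 selected, and a
15-model SVM bucket — sizes chosen so the full eight-combination grid and
the five-seed ensemble study complete in well under a minute while leaving
the full-scale defaults (H up to 100, 500 epochs, 50/12 bagging, 50-model
buckets) as the package defaults. The ensemble-versus-single comparison
trains five independent single networks per seed and compares the
ensemble's held-out accuracy against their median on the same test split.

## Known limitations

* The HOG cell/block pixel geometry on 4 x N images admits several
  layouts; the 5-cell half-span layout is this package's choice, with the
  81-length contract and 50% block overlap as the binding constraints.
* The 322-sample default corpus gives the TP53-deletion class only two
  samples (faithful to the emulated proportions), so per-class metrics for
  that class are unstable at desk scale.
* SCG is full-batch; very large corpora would need minibatching or a
  different optimizer.
* Single-substitution variants are near-identical to their reference in
  descriptor space; distinguishing them from the normal class is the
  hardest part of the synthetic task, as reflected in the confusion
  matrices.
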