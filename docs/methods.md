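# Methods

## The augmentation model

The package treats a regulatory sequence dataset as samples from a
function f: sequence → activity that is (approximately) invariant under
small evolutionary edits. Each augmentation perturbs a one-hot input while
keeping its labels, injecting a specific invariance assumption:

| transform | invariance assumed | hyperparameters (units: nt unless noted) |
|---|---|---|
| mutation | robustness to point substitutions | `mutate_frac` (fraction of positions changed) |
| translocation | motif order is not critical | `shift_min`, `shift_max` (roll magnitude) |
| insertion | motif spacing is not critical | `insert_min`, `insert_max` |
| deletion | motif spacing is not critical | `delete_min`, `delete_max` |
| inversion | local strand orientation is not critical | `invert_min`, `invert_max` |
| reverse complement | strand symmetry of activity | `rc_prob` (probability) |
| Gaussian noise | robustness to input perturbation | `noise_mean`, `noise_std` (matrix units) |

These assumptions are deliberately crude; where they are wrong, the
fine-tuning stage on unperturbed data lets the model unlearn them.

Exact sampling semantics worth knowing:

* **Mutation.** `n = round(L · mutate_frac / 0.75)` positions are drawn
  uniformly *with replacement*; each drawn position is resampled uniformly
  over the 4 letters. A resample keeps the original letter with
  probability 1/4, so the expected fraction of positions actually changed
  equals `mutate_frac`. Collisions are allowed (the last draw wins), so at
  large `mutate_frac` the realised change fraction falls slightly below
  the target. Draw counts are rounded (not floored); the cap at `L` warns.
  The alternative convention — forcing a different letter and dropping the
  0.75 correction — is *not* used.
* **Translocation.** Magnitude uniform on `{shift_min..shift_max}`, sign
  uniform on {+, −}, applied as a circular roll. Because −0 = +0, a
  configuration with `shift_min = 0` reaches the identity; the magnitude
  0 is not double-weighted (sign is applied after the magnitude draw).
* **Insertion.** Length `ℓ` uniform inclusive, insertion point uniform on
  `{0..L}` (both flanks allowed). The output length is always
  `L + insert_max`: the leftover `insert_max − ℓ` is added as uniform
  random DNA, `floor(p/2)` on the 5′ flank and the remainder on the 3′
  flank. "Random DNA" is uniform over the 4 letters everywhere.
* **Deletion.** Length uniform inclusive, start uniform on `{0..L−ℓ}`;
  the surviving flanks are concatenated in order and re-padded to length
  `L` with the same 5′/3′ split rule.
* **Inversion.** A length-`ℓ` block (start uniform on `{0..L−ℓ}`) is
  replaced by its reverse complement in place; at `ℓ = L` this equals the
  whole-sequence reverse complement.

Default settings come in two presets: `basset_defaults` (600-nt
accessibility models: `mutate_frac` 0.15, shift/insert/delete windows
0–30, `rc_prob` 0.5, `noise_std` 0.3) and `deepstarr_defaults` (249-nt
enhancer regression and the 200-nt TF-binding task: `mutate_frac` 0.05,
shift/insert windows 0–20, delete 0–30, `rc_prob` 0 — STARR-seq activity
is strand-specific). The inversion window is 0–30 (Basset preset) and
0–20 (DeepSTARR preset), chosen to match the scale of the other
window-length augmentations.

## Scheduling and the two-stage curriculum

Per mini-batch, every sequence independently draws a subset of the
configured augmentation set without replacement — `max_augs` of them in
`hard` mode, a uniform count in `{1..max_augs}` in `soft` mode (never 0:
a pretraining sequence always receives at least one augmentation) — and
applies it in the fixed priority order *inversion, deletion,
translocation, insertion, reverse-complement, mutation, noise*. The order
is a deterministic function of the drawn subset, so results do not depend
on draw order. When insertion is in the set, sequences that did not draw
one are 3′-padded with random DNA of length `insert_max`, keeping the
model input length constant; validation, test and variant-scoring inputs
get the same 3′ padding (and no other augmentation). Validation padding
content is seed-fixed per training run.

Pretraining uses Adam with lr 1e-3 and weight decay (L2) 1e-6 for up to
100 epochs, early stopping with patience 10, and lr decay by 0.1 when
validation loss stagnates for 5 epochs — the early-stop and decay
counters are independent, and "improvement" means any strict decrease of
the epoch-mean validation loss. Fine-tuning continues on unperturbed data
at lr 1e-4 for 5 epochs. Both stages return the minimum-validation-loss
checkpoint. Losses pair binary cross-entropy with sigmoid heads and mean
squared error with linear heads. Batch size defaults to 128;
miniature-scale experiments in this repository use 8, since with only a
few thousand sequences the number of optimizer steps, not epochs, limits
what five pretraining epochs can learn. Per-sequence augmentation RNG
streams are spawned from `(seed, epoch, batch index)` via numpy
`SeedSequence`, making runs bit-reproducible and independent of
batch-internal evaluation order.

## Architectures and the numpy backend

The model zoo describes networks as declarative layer lists (conv →
batch-norm → ReLU blocks, max pools, dense blocks, sigmoid/linear heads)
and builds them on an in-repo numpy backend with hand-derived backward
passes (verified against central finite differences to < 1e-7 in the test
suite). Pooled lengths follow `floor((len − size)/stride) + 1`, dropping
trailing remainders; flatten happens after the last pool. Shape inference
runs at build time and names the offending layer when a chain degenerates.
Weight init is He-uniform with a fixed seed; batch norm keeps exponential
running statistics (momentum 0.9) so inference is deterministic and
attribution gradients flow through an affine map. Growing `input_length`
by `insert_max` changes only the first dense layer's fan-in.

The miniature preset (`mini_cnn_spec`) is a single conv block (48 filters,
width 9) with a *global* max pool, a 32-unit dense block and a task head.
The global pool matters at desk scale: with a few thousand training
sequences, positional dense layers after mild pooling memorise the
training set instead of discovering motifs, whereas a position-invariant
readout generalises.

## Synthetic data

The generator emulates motif-implanted benchmarks: uniform-background
sequences, half labelled positive, each positive receiving each
configured motif with probability `embed_prob` at a uniform
(non-overlapping where possible) offset, instances sampled from the
consensus with an independent per-position substitution rate. Ground
truth (motif index, offset) is recorded per record. Defaults — 2,000
records of 200 nt, the AP-1-like 7-mer `TGACTCA` at substitution rate 0.1,
`embed_prob` 1 — give a planted signal of realistic strength: a matched
filter scores AUROC ≈ 0.92, so a small CNN can approach but not trivially
saturate the task. What the generator does *not* emulate: composite
grammars of interacting motifs, GC-content and repeat structure of real
genomes, label noise from peak calling, and class imbalance. Passing
tests therefore demonstrate that the machinery (augmentation, training,
recovery) behaves correctly, not that any architecture will match its
published performance on real assays.

Splits are random with fractions 0.7/0.1/0.2; floor-sized validation and
test partitions with the remainder assigned to training. N-containing
sequences are removed before splitting (and rejected outright at
encoding — no 0.25-uniform soft-encoding). Negative down-sampling for
binary peak tasks never up-samples.

## Variant-effect scoring

Effect size is the natural-log ratio of the task-mean prediction for the
alternative over the reference allele window. The log base is irrelevant
to ranking and Pearson correlation, which is how scores are evaluated:
one r per saturation-mutagenesis element, summarised by the unweighted
mean across elements; elements with fewer than two variants or zero
variance are flagged and excluded with a warning. Task aggregation is the
unweighted mean over all outputs (cell-type-agnostic); a task subset can
be passed explicitly. For insertion-trained models, ref and alt of a pair
share the identical random 3′ pad so the pad contribution cancels in the
ratio. Elements shorter than the model window are centred with the extra
base on the 3′ side.

## Interpretability

Filter PFMs use activation-based alignment: the raw first-layer
convolution response (pre-batch-norm, pre-ReLU) is scanned over a
sequence set — the test split by default; the choice of scan set is a
parameter — and windows with activation strictly above `threshold_frac`
(default 0.5) of that filter's maximum are stacked into per-offset letter
counts. Under strict `>` a filter whose only qualifying site is its own
maximum can return zero sites; such filters are reported with
`n_sites = 0` and skipped at MEME export with a logged notice. The MEME
minimal format is emitted with header `MEME version 4`, `ALPHABET= ACGT`,
both strands and a uniform background by default; round-tripping through
an independent MEME parser is part of the test suite. Users running
Tomtom against JASPAR downstream should note that low-information-content
filters match the profiles MA1929.1 and MA0615.1 promiscuously; excluding
those two profiles avoids inflated hit rates.

Attribution maps are single-sample expected gradients: per reference
(uniform random one-hot DNA, default 1,000 references), one uniform
interpolation point between reference and input is evaluated and
`(x − ref) ⊙ grad` accumulated. The gradient correction subtracts the
across-letter mean at each position, removing the direction that is
unidentifiable for inputs constrained to the simplex; it is idempotent
and leaves per-position letter sums exactly zero. High-activity sequence
selection for logo inspection is exposed as a percentile (default top 1%).

## Numerical and design choices

* Alphabet order is fixed to (A, C, G, T) everywhere; the complement map
  A↔T, C↔G is implemented in one-hot space as simultaneous reversal of
  both axes.
* Sequences are upper-cased on read; encoding rejects N and empty input.
* All stochastic operations take explicit `numpy.random.Generator`
  streams; a single integer seed reproduces datasets, training runs and
  augmentation draws bit-exactly on a fixed platform.
* Checkpoints embed the architecture spec (YAML) beside the weights so a
  model can be rebuilt without flags.

## Known limitations

* The backend is CPU/numpy and single-threaded beyond BLAS; it is built
  for correctness and desk-scale experiments, not for training the
  full-size presets on millions of sequences.
* Augmentation length distributions are uniform by design; no
  biologically calibrated indel spectra or transition/transversion bias.
* Multi-nucleotide variants and indel effect scoring are out of scope.
* Sequence-logo rendering is delegated to external tools (attribution
  maps export as TSV; PFMs as MEME).
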