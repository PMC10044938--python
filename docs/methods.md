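# Methods

## Sequence encoding

A length-L RNA over {A, C, G, U} is encoded as 146 binary L×L contact
matrices. The first 10 channels mark unordered base pairs: channel c holds a
1 at (i, j) iff {bᵢ, bⱼ} is the c-th of the 10 unordered pairs (order
insensitivity makes the features invariant to which strand contributes which
base of a contact). The remaining 136 channels do the same for unordered
pairs of dimers (2-mers): 16 dimers give 16·17/2 = 136 unordered pairs. The
dimer starting at the last position wraps to (b_L, b₁), so the terminal
row/column carries defined signal and circular RNAs encode naturally; the
dinucleotide channels have no wrap semantics (a single base needs none).

Choices the encoding fixes that the construction itself does not force:

* **Channel order** is lexicographic over the sorted pair members (bases
  A < C < G < U; dimers in 16-way lexicographic order). Any fixed order
  works; freezing one keeps saved model weights portable.
* **Diagonal cells** (i = j) are encoded like any others; the decoder's
  separation rule excludes them from ever pairing, and the network can
  learn to ignore them.
* **L = 1** is degenerate but well-defined (wrap dimer (b₀, b₀)); it is
  accepted with a warning.
* **Validation** is strict by default (only ACGU), since structures with
  unknown bases are usually excluded from curated benchmarks; a lenient
  mode maps T→U for DNA-style input.

For every cell exactly one dinucleotide and one tetranucleotide channel is
set, every channel is symmetric, and the full tensor sums to 2L² — these
partition/symmetry laws are asserted as property tests.

## Network

A fully-convolutional encoder-decoder over the 146×L×L input:

* **BCM** (basic convolution module): 3×3 same-padding convolution → batch
  normalization → ReLU.
* **Feature extraction**: three BCMs condensing 146 → 16 channels.
* **Encoder**: at each of 4 levels, a dense connected module (**DCM**) —
  a stack of BCMs where layer k consumes the concatenation of the block
  input and all previous layer outputs, and the block output keeps the
  input map — followed by a transition down (2×2 max-pool + BCM). With
  3-layer DCMs and growth rate 16 the depths run 16 → 64 → 112 → 160 → 208.
* **Bottleneck**: one DCM (without input concatenation).
* **Decoder**: at each level, transition up (2× nearest-neighbour
  upsampling + BCM projecting to the matching encoder depth), a residual
  skip-add of the same-resolution encoder map, then a DCM without input
  concatenation (depth returns to 48).
* **Head**: 1×1 convolution to one channel; the raw map is added to its
  transpose and batch-normalized, yielding a symmetric score map; the map
  is cropped back to L×L.

The default configuration stacks ~36–39 convolutions along the longest
path; per-block layer counts, growth rate and depth are all configurable.
Down/up-sampling operators (max-pool, nearest-neighbour) are the
conventional dense-segmentation choices. Inputs are zero-padded to a
multiple of 2⁴ = 16; padded cells are excluded from the loss and from the
final symmetrization statistics by masks (intermediate batch-norm layers
use plain batch statistics, as is usual in padded segmentation training).
Sequences beyond `max_length` (default 720) are refused rather than
truncated — extreme lengths are outliers at training time and would be
silently unreliable at prediction time.

The numeric core is a compact reverse-mode autograd on numpy. Convolution
is evaluated per kernel tap as one BLAS matmul over the padded grid with
shifted accumulation, keeping peak memory at O(C·H·W) instead of im2col's
O(C·k²·H·W) — the difference between feasible and not at L = 720 with 146
input channels. Weights are He-initialized from a seeded generator, so
model construction is deterministic; bitwise reproducibility across BLAS
builds is not asserted.

## Decoding

Structure prediction is the integer program

maximize ⟨S, P⟩ − ρ‖P‖₁ over symmetric binary P supported on the
constraint mask, with row sums ≤ 1 (at most one partner per base).

The mask admits canonical (A·U, C·G) and wobble (G·U) pairs at separation
|i − j| ≥ 4, i.e. hairpin loops of at least 3 unpaired bases. ρ (default
0.01) is a sparsity penalty: each added pair must carry score above ρ to
survive. ρ may be set negative, which turns the L1 term into a bonus and
reproduces the opposite sign convention some formulations print.

The relaxation (entries in [0, 1]) is solved primal-dually: projected
gradient ascent on P (symmetrize, clip to the box, zero off-mask each step)
against non-negative multipliers ascending on row-sum violations; defaults
are 200 iterations with steps 0.05/0.05. Rounding takes upper-triangle
cells with relaxed value ≥ 0.5 greedily in descending value (ties by
smallest (i, j)), skipping conflicts — feasible by construction for any
input. A final greedy completion adds admissible cells with s_ij − ρ > 0
whose bases are still free, in descending score order: a pure objective
improvement that recovers pairs whose relaxed mass was split between
same-row competitors and fell below the threshold. Without it the pipeline
reached the 1%-of-optimum mark on ~91% of random small instances; with it,
≥ 99% (measured against the exhaustive oracle below).

Because the feasible set is just a matching polytope restricted to the
mask — with no nesting constraint — crossing pair sets are first-class, and
the decoder returns pseudoknots whenever they score best.

`brute_force_optimum` enumerates all matchings of the allowed-cell graph
(each chosen pair contributes 2(s_ij − ρ)) and is the exact oracle for
instances up to L ≈ 14; the tests cross-check it against an independent
general maximum-weight-matching implementation before using it to judge the
pipeline.

## Metrics

Samples are bases. A base is positive iff paired in the reference; a
prediction counts TP only when the partner matches exactly; a base paired
to the wrong partner counts FN (the reference pair was missed), not FP.
This differs from pair-level scoring with slack used by some benchmarks and
is stated here prominently because it changes the numbers. ACC, SEN, PPV
and F-score follow the standard formulas; when a denominator is zero the
metric is reported as 0 and flagged. Dataset aggregation is micro (sum
counts, then ratios) by default, with a macro option. Cross-validation
splits are seeded round-robin partitions after a random permutation; fold
sizes differ by at most one.

## Training

The objective is class-weighted binary cross-entropy on the score-map
logits over valid cells (upper triangle, separation ≥ 4, inside the
un-padded square). Positives are rare (≈ L/2 of ≈ L²/2 cells), so they are
up-weighted by the per-batch valid/positive ratio, capped at 300. The
optimizer is Adam at learning rate 1e-3 (configurable); no schedule.
Records longer than `max_length` are skipped with a warning. Batches are
length-sorted to limit padding waste. Checkpoints keep the model with the
best validation F-score, evaluated every `eval_every` epochs through the
full decode pipeline.

These training choices (loss, optimizer, rate, epochs) are this package's
own declared defaults; they are deliberately minimal — a score map consumed
by a linear-objective decoder pairs naturally with a per-cell logistic
loss.

## Synthetic corpora

The fixture generator works structure-first: it recursively places stems of
3–6 stacked pairs with hairpin loops of ≥ 3 unpaired bases (so every pair
obeys the |i − j| ≥ 4 rule by construction — the generator must never emit
what the decoder forbids), then samples bases: paired positions from
{AU, UA, CG, GC} or, with probability `gu_fraction` (default 0.1), a G·U
wobble; unpaired positions uniform. With probability
`pseudoknot_probability` (default 0.3) one H-type pseudoknot — two crossing
stems, the minimal non-nested topology — is placed first. Defaults: 40
sequences of 30–70 bases.

What these corpora are for: exercising every code path (including crossing
pairs) with exactly known ground truth, offline and in seconds. What they
are not: thermodynamically realistic RNA. Paired regions are perfectly
complementary, lengths are short, and family/length statistics of curated
databases are not imitated. Consequently, a high training-set F-score on
fixtures demonstrates that the encoder, network, loss and decoder wire
together and that the model has the capacity to learn pairing structure —
it says nothing about accuracy on natural RNA, which requires training on
real curated corpora at much larger scale.

## Problem sizes

The shipped verification runs at desk scale, chosen so the whole suite and
the acceptance script each complete in minutes on one CPU: decoder
feasibility on 500–1000 random instances at L ∈ [20, 80]; near-optimality
on 200 instances at L ≤ 12 against exhaustive enumeration; network
contracts at L ∈ {17, 64, 100, 720}; learning sanity on 30 records of 30–60
bases for 100 epochs with a scaled-down configuration (16 feature channels,
2 levels, 2-layer DCMs, growth 8); format round trips on 1000 records.
Full-scale training on curated benchmarks is out of scope here.

## Known limitations

* Single-sequence input only; no alignment/covariance features.
* The decoder's one-partner constraint excludes base triples; only A·U,
  C·G, G·U pairs are representable.
* The primal-dual solve is approximate at its default iteration budget;
  feasibility is guaranteed unconditionally, optimality only empirically.
* Dot-bracket output supports four bracket tiers; deeper crossing nests
  (not produced by the H-type generator) are written lossily with a
  warning.
* CPU-only; throughput at L near 720 is seconds per sequence, not
  milliseconds.
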