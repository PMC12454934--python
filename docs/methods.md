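# Methods

`targetpep` detects and classifies eukaryotic protein targeting peptides —
the short sorting signals that route a protein to its compartment — at
single-residue resolution. Eight signal classes are covered, always in the
canonical order ER, PTS, MT, SP, CH, TH, NLS, NES, with an implicit ninth
OTHER category for unsignalled residues. This note records the model, the
procedures, the parameters that matter, and the design choices that were
genuinely open.

## Model

**Encoding.** A protein of length L is cut into fragments of
`fragment_length` residues (default 1022) at stride
`fragment_length − overlap` (default overlap 200); the final fragment is
truncated at the sequence end rather than re-anchored, so consecutive
fragments always share exactly `overlap` positions (re-anchoring would make
the shared region irregular; truncation keeps the invariant testable).
Each fragment is tokenized with a BEGIN (`<cls>`) and END (`<eos>`) token,
padded to batch width, and encoded by a transformer; the special-token and
pad rows are stripped so a fragment of n residues yields exactly n
embedding rows. Positions covered by more than one fragment receive the
arithmetic mean of their rows. The fragment/merge contract is
encoder-agnostic: any per-residue encoder with the same token discipline
can stand behind it.

**Test backbone.** The built-in backbone is a small trainable pre-norm
transformer (default 2 layers, width 64, 4 heads, feed-forward width 128,
ReLU in the feed-forward block) with three learned positional signals per
token: token identity, distance from the fragment start, and distance from
the fragment end. The from-end embedding exists because terminus-anchored
signals — the 4-residue ER retention signal and the 3-residue PTS1
tripeptide above all — are defined by their distance to the C-terminus,
information that absolute positions do not expose to a 2-layer model. A
residual local-convolution block (kernel 7, `local_conv_kernel`) sits on
top of the transformer stack: self-attention is notoriously imprecise at
exact relative-offset pattern matching, and the convolution gives every
residue's final state a crisp view of its 7-residue window, which the
position-wise heads need to pin short motifs to the residue. The
backbone trains in minutes on one CPU; it is a stand-in for a pretrained
protein language model in scale only, and the package makes no claim that
its embeddings resemble a pretrained model's.

**Heads.** Eight independent task heads consume the same merged embedding
matrix. NLS and NES use stacks of same-padded 1-D convolutions (kernels
7/11/15, 32 channels) because those signals are variable-length local
patterns at arbitrary positions; the six terminus-anchored classes use
position-wise 2-layer perceptrons (hidden width 128). Every head ends in a
per-position logistic unit, giving an 8 × L matrix of signal strengths in
[0, 1]. The logistic bias is initialised to −2 (`output_bias`), starting
every head near the background rate (~0.12) instead of 0.5: signal
residues are rare, and a prior-matched start lets the early gradient come
from the positives instead of being spent pushing ubiquitous negatives
down — without it, rare short classes routinely failed to lift off within
the desk-scale epoch budget. (`zero_init_output=True` still zeroes
everything, giving the all-0.5 diagnostic output.) The logistic outputs are independent across classes by
construction: a chloroplast transit peptide followed by a thylakoid signal
(CH+TH) must be representable simultaneously, which a joint softmax would
forbid. Head widths and kernel sizes are declared configuration defaults,
not estimates of any published architecture.

**Inference.** Per-residue calls take the vertical maximum over the eight
class strengths; the winning class c with strength m is called iff
m > 1 − m (equivalently m > 0.5), i.e. iff it beats its own implicit OTHER
complement — the rule introduces no free threshold beyond the OTHER
definition itself. Ties break toward the lower canonical class index, and
m = 0.5 exactly goes to OTHER (conservative, deterministic). Pure argmax
calling is available as `other_rule=False`. Runs of identical calls become
segments; the set of segment classes is the protein-level multi-label
call; cleavage sites are read off segment boundaries (far end for
N-anchored MT/SP/CH and for TH, which anchors at the CH boundary; start
for C-anchored ER/PTS, with PTS anchored to whichever terminus its segment
touches and C-terminal behaviour as the default).

## Losses and training

Two losses are summed. The residue-level loss builds a 9-row categorical
prediction by appending OTHER = 1 − columnwise-max to the 8 class rows and
renormalising each column to sum to one (renormalisation is required for a
proper categorical cross-entropy; the targets stay hard one-hot). Each
position is weighted by the inverse-frequency weight of its true class.
The protein-level loss takes the horizontal maximum of each class row
(masked to real positions), appends OTHER = 1 − max over classes, and
scores the 9 entries against the multi-label protein vector with weighted
binary cross-entropy.

Class weights are `N_total / (9 · N_c)` at both levels (protein counts
with OTHER = signal-free proteins; residue counts analogously), clamped to
[0.1, 10]; an absent class gets the clamp maximum with a warning. The
clamp keeps 3-residue signals from dominating the loss by three orders of
magnitude.

How a position picks its weight is configurable
(`residue_weight_mode`). ``"label"`` uses the true class's weight — pure
recall pressure, but a 100:1 weight ratio between a rare class and the
background also shifts the decision boundary toward false positives.
``"pred_max"`` weights a position by the class currently *selected as the
maximum* there, so a spurious rare-class winner carries that class's full
weight — strong precision pressure, but positions the model under-calls
fall back to the background weight and never get lifted. ``"max"`` takes
the larger of the two, applying recall pressure at true-signal positions
and precision pressure wherever a rare class fires; the recovery
experiment uses it because the other two modes measurably collapse to
over- or under-calling on the short C-terminal classes.

Each epoch regenerates the augmented training set (below), then optimises
with Adam (desk-scale learning rate 2·10⁻³ with a 0.93 per-epoch decay to
damp late-phase oscillation) over length-sorted batches capped at 16
proteins and ~6k padded positions. Each head is monitored on the
validation fold by its class-specific residue binary cross-entropy over
proteins carrying that class plus signal-free negatives, balanced between
positive and negative positions — without the balancing, a rare 4-residue
class drowns in its negatives and a head that outputs zero everywhere
looks converged. A head that fails to improve for `patience` consecutive
epochs is frozen; at the first head freeze the backbone freezes too
(configurable via `freeze_backbone_on_first`), the remaining heads restart
their best-tracking on the now-fixed encoder, and training ends when all
heads are frozen or `max_epochs` (default 200, patience 30) is reached.

Restoring "best" head weights needs care when the shared encoder is still
moving: a head snapshot is only meaningful against the backbone it was
taken with. The loop therefore restores a freezing head's best snapshot
only if it postdates the backbone freeze, and at the end of training each
remaining head keeps the best of (final state, best snapshot, Polyak/EMA
average of its weights, decay `ema_decay` = 0.995), decided by
re-validating every candidate against the final backbone — restoring
stale snapshots unconditionally was measurably destructive, and the EMA
candidate damps the epoch-to-epoch oscillation that per-epoch augmentation
noise induces in the rare-class heads. The desk-scale
recovery experiment disables `freeze_backbone_on_first`: with a
from-scratch encoder, freezing the backbone at the first (often
premature) head freeze starves every remaining head; the rule is kept as
the default for the pretrained-encoder setting it was designed for.
Instead the experiment freezes the backbone on a schedule
(`freeze_backbone_epoch`, mid-run): the heads then finish on a stationary
encoder, which measurably sharpens exact cleavage boundaries — heads
otherwise chase C-terminal representations that move under them every
epoch.

## Parameter-efficient fine-tuning

Three strategies configure backbone trainability; all are exact about what
they freeze, and each reports trainable/total parameter counts:

* **last-K** — only the last K transformer layers (plus the final layer
  norm) train; default K = 2.
* **LoRA** — the query/key/value projections of the last N layers are
  wrapped as h = W₀x + B(Ax) with rank r ≪ min(d, k); A starts as a small
  Gaussian and B at zero, so the wrapped model is bit-identical to the
  frozen base at initialisation, and only A and B train.
* **adapters** — bottleneck adapters (down-projection, GELU,
  zero-initialised up-projection, skip connection) are inserted twice per
  layer, after attention and after the feed-forward block, in the last N
  layers; zero-init makes each adapter the identity at insertion.

A fourth option, full fine-tuning, trains everything including the
embeddings. The desk-scale recovery experiment uses it because its
backbone is randomly initialised — freezing random weights would leave
nothing worth adapting; the PEFT strategies earn their keep only over a
pretrained encoder and are exercised here for their contracts (identity at
initialisation, exact freezing) rather than for accuracy.

## Data augmentation

Training proteins are replicated and point-mutated each epoch, from a
stream seeded by (seed, epoch): the same epoch regenerates identically,
different epochs differ. Positions inside annotated signals mutate with
probability 0.1, background positions with 0.3; a selected position
redraws uniformly from the 20 standard amino acids, so it keeps its
original residue with probability 1/20 and the effective change rate is
rate × 19/20. Replacement-only mutation never moves a span, so
annotations are reused verbatim. Copies per protein follow inverse-
frequency class weights `N_total / (K_nonempty · N_c)` scaled by
`replication_scale` and rounded half-up; a multi-label (CH+TH) protein
replicates by the maximum over its classes, not the sum, to avoid
compounding; signal-free proteins are not replicated. Copies inherit the
parent's fold: a 10–30% point-mutant is by construction similar to its
parent, so re-running identity control could only move it away from its
parent's fold and create leakage.

## Identity-controlled partitioning

Pairwise identity is matches / alignment-columns from a global
(Needleman–Wunsch/Gotoh) alignment with match +1, mismatch −1, gap open
−10, gap extend −1 (scoring configurable). Optimal alignments are not
unique and co-optimal alignments can disagree on match counts, so the
implementation fixes a canonical alignment by lexicographic objective:
maximal score, then maximal matches, then maximal aligned columns. The
three objectives are packed into one 64-bit integer per DP cell, so a
single pass yields the canonical identity without traceback; a numba
kernel handles the hot loop with a row-vectorised NumPy fallback.

Proteins at ≥ threshold identity (default 0.30) are joined in a graph;
single-linkage connected components are assigned whole to folds, largest
first into the currently smallest fold, with per-class counts as a soft
secondary objective. Single linkage is the only linkage under which the
cross-fold guarantee is exact, and `audit_partition` re-verifies it
exhaustively after every assignment.

## Synthetic data generator

The generator plants class-specific motifs into background sequences drawn
uniformly over the 20 amino acids (configurable). The grammar: ER is a
fixed C-terminal 4-mer (charged, acidic, acidic, L — KDEL-like); PTS a
fixed C-terminal tripeptide {S,A,C}·{K,R,H}·{L,M}; MT an N-terminal
20–40-mer, arginine-enriched and strongly net-positive, ending R-x-x-R;
SP an N-terminal 15–30-mer with positive n-region, L/I/V-rich h-region and
small-neutral c-region; CH an N-terminal 30–55-mer starting M-A and
enriched in S/T/A; TH a 12–25-mer placed immediately after a CH span
(twin-arginine start, S/A tail) — every TH protein therefore also carries
CH; NLS one to three internal 5–20-mer K/R blocks; NES an internal
10–22-mer, leucine-rich with D/E spacers. Composition tables are coarse
category mixtures chosen to make each class recoverable and mutually
distinguishable; they are not frequency estimates from real proteomes.

Defaults define the study conditions: 40 proteins per class, 20%
signal-free proteins (400 total), lengths uniform on [100, 180] with a 2%
tail of ≥1100-residue proteins so the fragment/merge path stays on the
training path, and optional planted near-duplicate clusters (5%
point-mutants) for exercising identity control. What passing tests on
this generator demonstrate is mechanism recovery — the pipeline can learn
and localise signals it is told exist under class imbalance — not
performance on real proteins, which carry homology structure, compositional
bias and annotation noise the generator deliberately omits.

## Desk-scale recovery experiment

`scripts/acceptance.py` (and the end-to-end test) run the full pipeline at
desk scale: 400 generated proteins, identity-controlled 5-fold
partitioning, and training of a 2-layer width-64 backbone with a 192/48
fragment grid — small enough that typical proteins are one fragment while
the ≥1100-residue tail exercises multi-fragment merging during training —
for at most 30 epochs with patience 6 and full fine-tuning, all seeded.
Held-out-fold metrics reported: protein-level macro-MCC and macro-F1 over
the eight classes, exact cleavage-site accuracy for terminus-anchored
classes, and NLS/NES segment overlap (SOV), with a permuted-segment
baseline for NLS (predicted segment lengths relocated uniformly at random,
20 shuffles). The whole experiment runs in roughly 6–8 minutes on one CPU.

## Evaluation

Protein-level MCC and F1 come from per-class confusion counts over
multi-label calls; MCC returns 0 when a denominator factor vanishes
(documented convention) and errors on an all-zero table. Cleavage-site
accuracy divides exact free-end matches by the number of proteins
*predicted* as the class; a never-predicted class is not-applicable, not
zero. SOV pairs each observed segment with its maximal-overlap predicted
segment (ties to the earlier predicted segment; no overlap contributes 0)
and scores min(OV, α·union)/Σ|S_obs| with α = 1 − ||S_obs|−|S_pred||/union;
the classical all-pairs SOV'99 variant is available via `sov_mode`. SOV is
averaged per protein, unweighted, within a class; table-level averages are
unweighted and truth-count-weighted across classes.

## Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over NumPy arrays (`_autodiff.py`) with
exactly the operations the model needs, plus the layers and the Adam
optimiser on top. Gradients of every operation and layer are verified
against central finite differences in the test suite. Float64 throughout;
loss probabilities are clamped at 10⁻⁷ before logarithms; max-gradient
ties split evenly (deterministic); all randomness flows through seeded
`numpy.random.Generator` streams, so every stage is reproducible from its
seed. Checkpoints are NumPy `.npz` archives carrying the config JSON, the
class order and a format version; loading rejects mismatches. PEFT-modified
architectures (LoRA/adapters) change the parameter tree and are not
round-trippable through a plain-config checkpoint — a known limitation.

## Known limitations

* The test backbone's embeddings carry no evolutionary information; real
  accuracy claims require a pretrained encoder behind the same contract.
* Exact cleavage-site accuracy is the hardest desk-scale quantity. For
  the variable-length N-terminal classes (MT, SP, CH, TH) boundary
  prediction needs more training signal than 30 epochs on 400 synthetic
  proteins provide. The fixed-length C-terminal classes (ER, PTS) detect
  their spans well (protein-level MCC ~0.7, most true spans recovered
  exactly) but plateau near 0.5–0.6 exact-site accuracy: substitution
  augmentation at the configured rates corrupts roughly a third of each
  epoch's 3–4-residue motif copies while keeping the positive label, so
  the training distribution itself teaches partial-match tolerance — the
  resulting sporadic false-positive calls enter the accuracy denominator
  (which counts predicted proteins), and suppressing them costs recall
  instead. A larger encoder, longer training, or augmentation that spares
  ultra-short signals would be needed to push past this plateau.
* Insertions/deletions are not modelled in augmentation; nested or
  overlapping signals are rejected by design.
* The generator's homology model (point-mutant clusters) is far simpler
  than real family structure; the partition guarantee is exact regardless,
  but fold difficulty on real data will differ.
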