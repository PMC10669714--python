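# Methods

## Problem

Noncoding RNAs (tRNA, rRNA, snoRNAs, ribozymes, riboswitches, IRES
elements, ...) within one family tend to share function, so assigning a
novel transcript to a family is a useful first annotation step.
Structure-based classifiers (covariance models, graph features over
predicted secondary structure) struggle with pseudoknots and are limited
by the quality of the structure prediction.  `confrna` implements a
sequence-only deep classifier in the ConF style: the only input is the
nucleotide string over {A, C, G, U}.

## Model

### Representation

A sequence of length n is decomposed into its n−k+1 overlapping
(stride-1) k-mers, k = 2 by default.  Each k-mer maps to an integer by
lexicographic enumeration (A<C<G<U), giving a 4^k-token vocabulary plus
one pad token.  Token sequences are right-padded (or truncated, keeping
the 5′ prefix) to a fixed window of L = 224 and embedded into 16
dimensions; both the k-mer and pad embeddings are learned.  No attention
masking is applied to pad positions — the pipeline is a fixed-length
one, and the pad embedding is itself trainable.

The "k-mer frequency" view of the representation is deliberately *not*
used to order the vocabulary: indices are fixed lexicographic, and all
distributional information is learned by the embedding.  (The
alternative — frequency-ranked indexing — would make token identity
dataset-dependent, breaking checkpoint portability.)

### Front-end

Two branches read the embedded sequence in parallel:

- a BiLSTM with 16 hidden units per direction.  Gates follow the
  standard equations f_t = σ(W_f·[h_{t−1}, x_t] + b_f), likewise for the
  input and output gates, candidate c̃_t = tanh(W_C·[h_{t−1}, x_t] + b_C),
  C_t = f_t∗C_{t−1} + i_t∗c̃_t, h_t = o_t∗tanh(C_t).  Forward and
  backward hidden states are concatenated per position → 224×32;
- a dual-layer CNN: two stacked same-padded convolutions, kernel 5,
  ReLU, 96 filters each.  The filter count is chosen so that
  32 + 96 = 128, the model width quoted for the concatenated front-end
  (224×128).  The kernel size of this branch is a free design choice and
  is configurable.

### Attention-based residual fusion

Everywhere a residual connection appears, plain addition H(x) = F(x) + x
is replaced by cross multi-head attention: the shallow features supply
the queries, the deep features supply keys and values, and the attended
result is added to the shallow path:

    fuse(x, F(x)) = x + MultiHead(Q = x, K = F(x), V = F(x))

with scaled dot-product similarity softmax(QKᵀ/√d_head)·V per head, h = 4
heads by default, and per-head width d_model/h.  Setting the output
projection W^O to zero recovers the identity mapping on the shallow
path exactly — the classic "F(x) can be set to zero" property of
residual blocks — which is asserted bitwise in the tests.  Queries come
from the shallow side because the fused result must preserve (and be
aligned with) the shallow features.  No positional encoding is added
inside attention; sequence order information is carried by the BiLSTM
branch.

The first fusion compares the front-end features with their transform
under a position-wise two-layer MLP (ReLU between the layers).

### Multi-scale residual blocks and downsampling

Block1's deep path runs three parallel same-padded convolutions over its
128-channel input — window 16 (undilated) and windows 10 and 18 at
dilation 2 — concatenates them channel-wise, and projects back to 128
channels with a width-1 convolution; the result is fused with the block
input through cross attention.  "Scale of 16" is read as the convolution
window (parallel to the quoted windows 10 and 18), not the filter count;
the dilation rate of 2 for the two dilated branches is a design choice
(unspecified in the source architecture), both configurable.  The
width-1 projection exists because three concatenated branches must
re-enter a residual of the original width; a 1×1 convolution is the
standard way to do that.

Downsampling is a lossless positional reshape: positions (2t, 2t+1) are
stacked channel-wise into position t, so 224×128 → 112×256 and the
inverse reshape recovers the input exactly.  Block2 repeats Block1's
structure at the doubled width (256 channels, branch filter counts
doubled accordingly).

The classifier head global-average-pools over positions, applies one
hidden fully connected layer (ReLU) and a softmax over the 13 families.
Pooling (rather than flattening) keeps the head parameter count
independent of the window length.

### Numerical core

No tensor/autodiff framework is used: the package carries a compact
reverse-mode automatic differentiation engine over numpy arrays
(`confrna.autograd`), written for exactly the primitives this model
needs — broadcast arithmetic, matmul, the sigmoid/tanh/ReLU/softmax
nonlinearities, gather-based embedding, and same-padded dilated
convolution via an im2col gather with a scatter-add backward.  All
computation is float64, which makes runs bitwise reproducible across
identical seeds and lets the finite-difference gradient check hold a
1e−4 relative tolerance.  The BiLSTM scan fuses the four gate matmuls
and precomputes all input projections outside the time loop; a test
asserts the fused scan equals the literal per-step cell to 1e−10.

## Training

Categorical cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), learning rate
0.001, 220 epochs, batch size 200 are the configured defaults.  The
optimizer choice is ours — only the learning rate, epoch count, batch
size and loss are fixed by the reference recipe — and no early stopping,
learning-rate schedule, weight decay or other regularization is applied;
any late-epoch accuracy dip is accepted behavior.  Model initialization
(Glorot uniform; zero biases; N(0, 0.1²) embeddings) and batch order are
derived deterministically from (seed, fold index).

Evaluation protocols, all seeded and all accepting a pluggable fold
trainer:

- **ten-fold cross-validation** — stratified folds (shuffle within
  family, deal round-robin), so per-family fold counts differ by at most
  one and every record is tested exactly once.  Stratification is a
  design choice: with one family 36% the size of the rest, unstratified
  folds would have unstable compositions.  Aggregate metrics are
  unweighted means over folds;
- **k-mer sweep** — one cross-validation per k ∈ {1, 2, 3} with identical
  fold plans and seeds across k, summarized by box-plot statistics
  (quartiles via linear interpolation between order statistics);
- **robustness protocol** — the dataset is partitioned into five
  disjoint stratified subsets, each cross-validated with a distinct
  derived seed, yielding five accuracy distributions.

## Metrics

One-vs-rest per class: accuracy (TP+TN)/(TP+FP+FN+TN), sensitivity
TP/(TP+FN), precision TP/(TP+FP), and F1 = 2TP/(2TP+FP+FN), i.e. the
harmonic mean of precision and sensitivity (the standard form; a test
asserts F1 ≡ 2PR/(P+R) to 1e−12).  Macro averaging is the default, with
micro also exposed; plain correct/total is always reported as "overall
accuracy".  In single-label multiclass classification micro precision =
micro sensitivity = overall accuracy — an identity the tests assert,
and the reason benchmark tables sometimes print accuracy equal to
precision.  0/0 metric ratios are reported as 0 with a warning flag.
Family-to-family relationships are summarized by the Pearson correlation
of per-fold F1 columns (Pearson chosen over Spearman; with ~10 folds the
rank statistic is too coarse); zero-variance columns yield missing
values.

## Synthetic data

The generator exists so that every stage — I/O, folds, training,
protocols — is testable without external downloads.  Each family is a
recipe: a triangular sequence-length law, a background nucleotide
composition, and motifs planted at uniform positions with a per-site
substitution rate applied to each planted copy.

`generate_rfam_like` emulates the benchmark composition this model
family is evaluated on: 13 families named after the real ones
(miRNA, 5S_rRNA, 5.8S_rRNA, ribozyme, CD-box, HACA-box, scaRNA, tRNA,
Intron_gpI, Intron_gpII, IRES, leader, riboswitch), the IRES analog
under-represented at 320 sequences and the other twelve at 500 each
(6320 total).  Lengths follow a triangular 50–400 nt law (mode 150) so
that a substantial fraction of sequences falls on each side of the
224-token window, exercising both the padding and the truncation path;
the real benchmark's per-family length distributions are not recoverable
from its description, so this law is schematic.  Each family carries
three 10-nt motifs planted with probability 0.9 under a 5% per-site
substitution rate, over a family-specific Dirichlet(6,6,6,6) composition
tilt.  A master seed spawns per-family child seeds, so generation is
deterministic and byte-identical per seed.

What the generator does *not* emulate: covariance structure (paired
stems), secondary structure of any kind, length–family correlation
beyond the shared law, shared motifs between related families, or
sequencing noise.  Passing tests on this data therefore demonstrate that
the pipeline can discover planted sequence signal end to end — not that
it reaches any particular accuracy on real Rfam families.

A 2-mer nearest-centroid baseline (`confrna.baselines`) certifies
learnability: on the emulated benchmark it scores well above chance
(≈0.84 held-out vs 1/13 ≈ 0.077), and its accuracy decreases
monotonically as the motif substitution rate rises when composition
signal is removed.

## Scaled-down study sizes

Desk-scale runs (tests and the acceptance script) use:

- an easy 4-family task: 200 sequences per family, 60–130 nt, three
  always-planted 10-nt motifs per family at a 2% substitution rate, and
  rotated background compositions (one nucleotide at 0.4);
- a narrow model (`small_config`): window 96, embedding 8, BiLSTM 4+4,
  8-filter CNN branch (d_model 16), block kernels 8/5/9, two heads —
  the same topology at reduced width;
- 30 epochs, batch 64, a single held-out fold of a ten-fold plan.

A from-scratch run under these conditions reaches held-out macro-F1
≈ 0.99 with training loss falling from ≈1.38 to ≈0.03.  The full-width
configuration (224-window, 128-channel, 13-class) is exercised
shape-and-gradient-wise in the tests; training it to the reference
accuracy (~0.96 on the real 6320-sequence benchmark) requires the real
Rfam-derived data and long stochastic training, and is out of scope.

## Degenerate inputs and edge rules

- T is normalized to U and case is folded on ingest; IUPAC ambiguity
  codes are rejected with the record id and offending position.
- Sequences shorter than k cannot be tokenized and raise an error.
- Even-span same-padding puts the smaller overhang on the left.
- A fold plan requires every family to have at least `n_folds` members.
- Metric ratios with zero denominators are 0-valued and flagged.
- Checkpoints are an `.npz` parameter archive plus a YAML config
  sidecar; loading validates shapes against the configuration.

## Known limitations

- Pure-numpy training is CPU-bound and single-threaded; the full-width
  configuration trains orders of magnitude slower than a GPU framework
  implementation would.
- No attention masking of pad positions; very short sequences in a long
  window dilute attention over trained pad embeddings.
- The synthetic generator's motif signal is far easier than real family
  structure; accuracies on it say nothing quantitative about Rfam.
- Truncation keeps the 5′ prefix; 3′-distal signal in long sequences is
  discarded.
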