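# Methods

## Model

A protein of length `L` is mapped to a per-residue representation
`H ∈ R^{L×d}`, pooled to a single vector by supervised attention, and
classified by two independent multi-label heads.

**Embedding providers.** The embedding stage is a contract, not a fixed
architecture; three providers implement it:

- `onehot` — 21 indicator dimensions (20 canonical residues + X). Attention
  scores then depend only on residue identity, so this provider is a
  baseline, not a motif detector.
- `conv` — a trainable encoder: a residue embedding table (default 32
  dimensions) followed by two width-7 convolution + ReLU layers (default 128
  channels). Two stacked width-7 layers give a 13-residue receptive field,
  enough to cover the short contiguous motifs that sorting signals form;
  it is the smallest encoder with which the attention can localize them.
- `precomputed` — matrices computed outside the package (for instance by a
  pre-trained protein language model), stored one `.npy` per sequence with a
  manifest CSV. The classifier then trains only the attention vector and the
  heads, which is the intended configuration when strong embeddings are
  available.

Sequences longer than `max_length` (default 1022) are truncated keeping the
first ⌈max/2⌉ and last ⌊max/2⌋ residues. Both termini are kept because
sorting signals are predominantly terminal; signal masks are truncated with
the same index map so supervision stays aligned.

**Attention pooling.** Raw scores `s_t = v·h_t` are smoothed with a 5-tap
Gaussian kernel at offsets −2..+2 with σ = 2 positions — i.e. the kernel is
clipped at one standard deviation — then passed through a numerically stable
softmax, and the sequence representation is the weighted sum `z = Hᵀa`.
The smoothing encodes the prior that signals occupy contiguous runs of
residues; a single-residue score spike is diluted, a 5-residue run is not.
At the boundaries, out-of-range taps are dropped and the remaining taps are
renormalized to sum 1. This choice keeps the operator linear, constant-
preserving (a constant score vector smooths to itself, so the termini are
not biased), and commuting with sequence reversal. The kernel width and σ
are configurable; other readings of "width 5 clipped at one standard
deviation" (e.g. a different tap count at fixed σ) can be expressed through
those knobs.

**Heads and losses.** Each head is an MLP with one hidden ReLU layer
(default width 256) and per-label sigmoid outputs — no softmax across
labels, since label sets are not mutually exclusive. Training minimizes a
weighted focal loss per label, averaged over labels:

    FL_c = −α_c (1−p_t)^γ log p_t,   p_t = p_c if y_c = 1 else 1−p_c

with γ = 2 (the canonical focal exponent) and α_c the inverse training
frequency of label c normalized to mean 1, which counters the heavy class
imbalance of localization corpora. Probabilities are clamped at 1e-7 before
the logarithm.

**Attention supervision.** For sequences with annotated signal residues the
stage-1 loss adds `λ_attn · KL(q‖a)` with `q` uniform over the annotated
residues (mean over the annotated sequences in the batch, weight default
1.0). This direction of the KL penalizes attention that misses annotated
residues; it is also the direction used in the evaluation diagnostics, so
training and evaluation agree. Sequences without signal annotation
contribute nothing to this term.

**Two-stage training.** Optimizing both tasks jointly is unstable, so the
localization head, the attention vector and the encoder are trained first
(stage 1); then every parameter outside the signal head is frozen and the
signal head is trained on the pooled representations (stage 2). Because the
pooled vectors are fixed in stage 2, they are computed once and the stage
reduces to training a small MLP. The freeze contract is enforced by test
(hash equality of all frozen parameter groups before/after stage 2).
Optimization is Adam (default learning rate 1e-3) with mini-batches padded
per batch, early stopping on validation micro-F1 with patience 5, and the
best-validation parameters restored. All gradients are derived by hand in
NumPy and verified against central finite differences in the test suite.

**Decision rule.** Per-label thresholds are fitted on training data by
maximizing MCC over the candidate set {0, 1, midpoints of consecutive
sorted unique scores}; ties break toward the smaller threshold. The
comparison is inclusive (`p_c ≥ τ_c`), which makes behaviour at exact
equality deterministic. If no label crosses its threshold the single label
maximizing `p_c − τ_c` is chosen (ties to the lowest label index), so the
decided set is never empty and the mean predicted label count is ≥ 1.

## Metrics

- exact-match accuracy: fraction of proteins whose decided set equals the
  true set — the strictest multi-label accuracy convention; users comparing
  against per-label accuracies should expect lower numbers;
- Jaccard: mean per-protein |∩|/|∪|, with the (unreachable) empty/empty
  case defined as 1 so the metric is total;
- micro-F1 from pooled counts, macro-F1 as the unweighted label mean with
  F1 = 0 for labels with neither positives nor predictions;
- per-label MCC with the 0-denominator convention (returns 0);
- per-label ROC AUC by the rank formula, ties counted ½;
- attention/signal agreement: KL(q‖a) per signal type, with q uniform over
  that type's annotated residues; mean ± sd across proteins. Empty masks
  are excluded (the value is undefined).

## Curation and homology partitioning

The training-corpus filter retains entries that are eukaryotic, not
fragments (fragments may have lost terminal sorting signals), encoded in
the nucleus, strictly longer than 40 residues, and carry at least one
sublocation term with experimental evidence (ECO:0000269) that maps into
the ten-class vocabulary; the label set is the union of the mapped classes.
Evidence is required per term, so non-experimental terms never contribute
labels. The independent-benchmark filter keeps only the two highest
microscopy reliability grades (Enhanced, Supported) and maps into the six
compartments such benchmarks resolve. The free-text term → class mapping
ships as an editable CSV covering common terms; it is a working default and
callers may substitute their own.

Global identity is Needleman–Wunsch with BLOSUM62, gap open 11, gap extend
1, terminal gaps penalized; identity = matches / alignment length
*including gap columns* — the stricter of the common conventions and the
one that remains well-defined for unequal lengths. Pairs are aligned in a
canonical order so identity is exactly symmetric even when co-optimal
alignments exist. Sequences with identity strictly above 0.30 are linked;
connected components are assigned whole to folds, largest first, each to
the currently smallest fold (ties to the lowest index). This guarantees
zero cross-fold homologous pairs; balance is best-effort (the fold-size
spread is bounded by the largest component, and an oversized component is
logged, not rejected). Label-stratified balancing is not implemented; the
all-pairs path is quadratic and intended for corpora up to a few thousand
sequences.

## Synthetic generator

The generator emulates the structure of a curated localization corpus:
background residues from SwissProt-like frequencies, 0–2 planted motifs per
sequence at realistic positions, deterministic signal → label rules (e.g.
SP → Extracellular, SP+TM → Cell membrane, MT → Mitochondrion,
NLS → Nucleus, a "shuttling" NLS variant → Nucleus + Cytoplasm, no signal →
Cytoplasm), a label-noise rate (default 0.02: one uniformly chosen label
toggled, never emptying the set), multi-location proteins via two-label
rules, and optional homologous families (mutated copies at ~94% identity
whose planted signals are left intact so labels stay consistent). The
default 10-class configuration has an expected mean of ≈1.27 labels per
protein, matching real multi-location corpora; `expected_label_stats`
returns the closed-form expectation against which the empirical corpus is
tested. Ground-truth masks equal the planted intervals exactly.

What the generator does **not** emulate: real signal-peptide biophysics,
evolutionary covariation, length/composition biases of specific organisms,
and annotation incompleteness. Passing the recovery experiment therefore
shows that the architecture, losses, thresholds and attention supervision
work as specified on corpora whose signals are learnable and contiguous —
it does not certify accuracy on natural proteins, which additionally
requires strong embeddings (the `precomputed` provider) and real curated
data.

## Desk-scale experiment

The bundled experiment (`protloc.benchmark.run_desk_experiment`, also run
by `scripts/acceptance.py`) uses n = 2000 sequences of length 100–200, six
localization labels driven by four signal types (SP, TM, MT, NLS), balanced
5-fold assignment by family with fold 4 held out and fold 3 for early
stopping, and a deliberately small model (conv channels 32, embedding table
16, hidden 64, learning rate 2e-3, ≤60 epochs, patience 10): the corpus is
small and the motifs short, so the library-default sizes only cost time.
The partition-soundness check uses a 120-sequence corpus of 4-member
families and exhaustive pairwise alignment. These problem sizes are the
package's chosen desk-scale study conditions; the library itself has no
such limits.

## Numerical conventions and edge cases

- Coordinates: 1-based closed intervals in files, 0-based half-open in
  memory; conversion only at the I/O boundary.
- Non-canonical residues (B, Z, J, U, O) fold to X with a warning; other
  unexpected characters are masked to X or rejected per configuration.
- Softmax is max-subtracted; KL sums only over the support of q; focal
  probabilities are clamped at 1e-7.
- Degenerate threshold fitting (a label with one class only) defaults to
  τ = 0.5 and is logged.
- Batch padding is masked out of every sum; convolutions read zeros beyond
  the boundary, and smoothing renormalizes over in-range taps, so padded
  and unpadded computations agree.
- Determinism: a single integer seed fixes corpus, initialization, batch
  order, and therefore all outputs bit-for-bit on one machine.

## Known limitations

- No pre-trained language-model weights are shipped; with the small conv
  encoder the model learns motifs present in its training data only.
- The sublocation mapping CSV is a pragmatic default, not a controlled
  vocabulary.
- Fold balancing ignores label composition.
- The webserver-style 500-sequence cap is only a warning in the CLI, and
  there is no job queue or web frontend.
- Stage-2 freezing means signal-type performance is bounded by how much
  signal information stage 1 stored in the pooled representation.
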