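# Methods

`rpistack` predicts whether a non-coding RNA and a protein interact,
using only their sequences. This note documents the model, its
parameters and defaults, the synthetic benchmark generator, and the
numerical choices made where the design was genuinely open.

## Feature construction

**Proteins — PSSM bi-gram transitions.** Each protein is represented by
a position-specific scoring matrix (PSSM) with one row per residue and
20 columns, produced by iterative BLAST searches against a protein
database (this package parses the PSI-BLAST `-out_ascii_pssm` dialect;
it does not run PSI-BLAST). The integer observed-percentage block is
normalized row-wise into a row-stochastic matrix P = {p_ij}, p_ij being
the relative probability of amino acid j at position i (rows sum to 1
within 1e-9; an all-zero row — a position with no database hits — falls
back to the uniform row 1/20, surfaced as the `percentages` mode's
documented degenerate-input rule). An alternative `softmax` mode
exponentiates the log-odds block instead, for profiles with a missing
or degenerate percentage block; `percentages` is the default because
the normalized frequencies are already probabilities. The bi-gram
encoder computes expected consecutive-position transitions

    b_mn = Σ_{i=1..r-1} p_im · p_{i+1,n},   1 ≤ m, n ≤ 20,

flattened row-major into a 400-dimensional vector F. Because P is
row-stochastic, Σ_mn b_mn = r − 1 exactly; this identity is asserted on
every extraction (tolerance 1e-6) and doubles as an internal
correctness check. F is *not* divided by r − 1 by default — the
transition-mass definition is kept literal — but a `length_normalize`
flag exposes the scaled variant for length-heterogeneous corpora.

**RNAs — positional k-mer matrix and singular values.** An RNA of
length L becomes a binary occurrence matrix M with 4^k rows (k-mers in
lexicographic order, A<C<G<U) and L−k+1 columns (sequence windows);
entry a_ij = 1 iff window j spells k-mer i. Windows containing a
non-ACGU base give an all-zero column, preserving positional register
instead of truncating. k defaults to 4. The fixed-length feature vector
is the descending vector of the top-d singular values of M (d = 16
default), zero-padded below the rank. Note that M·Mᵀ is diagonal — its
entries are the k-mer occurrence counts — so the singular values are
the sorted square roots of those counts: a spectral, position-free
summary of k-mer usage whose length does not depend on L. Left singular
vectors or projections would carry k-mer identity as well, but have
rank- and sign-ambiguity and L-dependent scaling; the singular values
were chosen as the simplest well-defined fixed-length reduction.

## Sparse stacked auto-encoder

Hidden-level codes come from a stack of sigmoid auto-encoder layers
(default widths 256, 128 on the 416-dimensional concatenated input).
Each layer minimizes the sum-over-samples objective

    Σ_i ‖x̂(x_i) − x_i‖² + α‖W‖² + β Σ_j KL(p ‖ p̂_j),

with KL(p‖p̂) = p·ln(p/p̂) + (1−p)·ln((1−p)/(1−p̂)), p̂_j the mean
pre-dropout activation of hidden unit j over the minibatch (clipped to
[1e-8, 1−1e-8] before evaluation). Defaults: sparsity target p = 0.05,
weight decay α = 1e-4, sparsity weight β = 3 — conventional sparse
auto-encoder settings; dropout probability 0.5, minibatch size 100 and
100 epochs follow the training protocol this model family is normally
run with. Inputs are min–max scaled per feature to [0, 1] (the sigmoid
decoder's range), with the scaler fitted on training folds only.

Numerical choices:

* Losses are reported in sum-over-samples form, but parameter updates
  divide gradients by the minibatch size so the learning rate
  (default 0.01) acts per sample regardless of batch size.
* The sparsity statistic p̂ is computed from the clean (pre-dropout)
  activations. Computing it from inverted-dropout-scaled activations
  (entries up to 1/keep) lets p̂ exceed 1, and the clipped KL gradient
  then explodes; the clean-activation convention avoids this and
  matches standard sparse auto-encoder practice.
* Layers are trained greedily: layer ℓ auto-encodes the encoded output
  of layer ℓ−1. Weights use Glorot-uniform initialization; biases start
  at zero; all randomness flows from a single seeded generator, so a
  given configuration and seed reproduce bit-identical models.
* Training aborts with a diagnostic if the loss becomes non-finite.

**Fine-tuning.** A single sigmoid output unit is attached and a binary
cross-entropy loss is back-propagated through every encoder layer
(decoders are frozen; dropout stays active at train time). The
supervised phase is optimized with Adam (learning rate 5e-3, β₁ = 0.9,
β₂ = 0.999, deterministic given the seed): within the fixed 100-epoch
budget, fixed-step gradient descent leaves the supervised loss — and
therefore the representation — essentially unchanged at every stable
step size, so an adaptive step is required for fine-tuning to do
anything at all. Pre-training keeps plain minibatch gradient descent,
which demonstrably decreases its objective (asserted in tests). The
reconstruction target of the unsupervised phase is the input itself
(y⁽ⁱ⁾ = x⁽ⁱ⁾); fine-tuning swaps in the true labels.

## Base predictors and stacked fusion

Three level-0 predictors score each pair from the concatenated
protein + RNA feature vector, all using 500-tree random forests with
sqrt-features per split (seeded): `RPIseq-RF` on raw features, `SA-RF`
on pre-trained auto-encoder codes, and `SA-FT-RF` on codes from the
same auto-encoder after supervised fine-tuning (the two share one
pre-training run; fine-tuning operates on a copy). A level-1 logistic
regression P(y=1|s) = σ(wᵀs + c) fuses the three probability outputs.
It is fitted **only on out-of-fold level-0 scores** from an internal
stratified 5-fold split of the training data — stacking fitted on
in-fold scores learns the base models' training optimism rather than
their skill. The level-1 fit is unregularized, falling back to ridge
(C = 1) if perfect separation produces non-finite coefficients. With
equal weights the fusion reduces to average-score voting; with one
non-zero weight, to that base model alone. Classification thresholds
fused probability at 0.5, ties counting as interacting.

## Evaluation

Stratified five-fold cross-validation (stratification guards the
imbalanced benchmarks this method targets), with every fitted component
— scaler, auto-encoder, forests, level-1 combiner — trained inside each
training fold. Reported metrics: accuracy, sensitivity, specificity,
precision, MCC (zero-denominator convention: MCC = 0) and trapezoidal
ROC AUC (equal to the midrank Mann–Whitney statistic). Both the
across-fold mean and the pooled-prediction metrics are reported, since
published cross-validation tables rarely state which convention they
use. Pair rows are canonicalized by id before folding so results do not
depend on input row order.

## Synthetic benchmark generator

The generator emulates the structure of the public RNA–protein
interaction benchmarks (hundreds of pairs over modest sequence pools)
with a planted, tunable ground truth:

* a fraction of proteins (default 1/2) carries a conserved amino-acid
  motif (default 8 residues); a fraction of RNAs carries a base motif
  (default 8 bases) inserted in several copies (default 4) — repeated
  occurrences emulate recurring binding sites, and are what the
  singular-value spectrum can actually see, since a single extra
  window barely moves the sorted k-mer counts;
* a pair interacts with probability `signal_strength` (default 0.95)
  if both partners carry their motifs, and with probability
  1 − `signal_strength` otherwise; at 0.5 the labels are coin flips;
* the fraction of sampled pairs with both motifs is solved from
  f·s + (1−f)(1−s) = `positive_fraction`, so the label marginal matches
  the requested positive fraction at any signal strength;
* pseudo-PSSM rows are Dirichlet draws sharpened at the true residue
  (concentration 12 by default), written in the PSI-BLAST ASCII dialect
  (percentages = rounded 100·p; log-odds = rounded 2·log₂(p/0.05));
  identical configurations yield byte-identical files.

Default study conditions: 400 pairs over 40 proteins × 160 RNAs,
protein lengths 60–120, RNA lengths 80–160, balanced labels. A `hard`
preset (5-residue motif, single-copy 4-base RNA motif, concentration 2,
signal 0.9) emulates a benchmark where raw and unsupervised-code
features struggle.

What the generator does **not** emulate: real PSI-BLAST statistics
(E-values, information content), sequence homology structure,
compositional bias, secondary structure, or binding determined by
anything other than motif co-occurrence. Passing tests therefore show
that the pipeline recovers a planted sequence-motif signal under
realistic dataset sizes and noise — not that it reaches any particular
accuracy on real interaction data.

## Standing experiments and problem sizes

Three frozen studies (in `rpistack.experiments`) exercise the full
pipeline end to end at desk scale:

* **Signal recovery** — five-fold CV of the stacked ensemble on the
  default 400-pair study; the planted-signal expectation is mean
  AUC ≥ 0.9.
* **Permutation null** — out-of-fold AUC of the raw-feature base model
  after permuting the labels of the same study; expected ≈ 0.5. The
  raw-feature model is used because a permutation null does not depend
  on which downstream feature transform is attached.
* **Fine-tuning contrast** — hold-out AUC of SA-RF vs SA-FT-RF on the
  hard preset with a deliberately narrow code (hidden widths 32, 4):
  the weak planted signal does not survive unsupervised compression
  through a 4-unit bottleneck, and supervised fine-tuning restores it,
  reproducing the published ordering of the two auto-encoder base
  models on hard data. The contrast averages five independently
  generated datasets and 70/30 stratified splits, because a single
  120-pair holdout cannot rank base models reliably.

These problem sizes (400 pairs, five folds, five repetitions) keep each
study's full run in minutes on a single core while leaving the planted
effects well clear of their decision thresholds.

## Known limitations

* The PSSM parser supports only the 40-column PSI-BLAST ASCII layout;
  other dialects are rejected loudly rather than guessed at.
* Singular values discard k-mer identity (M·Mᵀ is diagonal); RNAs with
  identical k-mer count multisets are indistinguishable to the RNA
  channel by construction.
* The auto-encoder is a plain dense sigmoid stack: no denoising or
  convolutional variants, no early stopping, no GPU path.
* The level-1 combiner sees only three scores; its weights are
  interpretable but their sampling variance at a few hundred training
  pairs is substantial.
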