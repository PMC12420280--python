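# Methods

## Problem and model

`deepcatcr` classifies TCR β-chain CDR3 amino-acid sequences as
cancer-associated or not, and aggregates per-sequence scores into
donor-level cancer predictors. The sequence classifier is a small neural
network:

1. **Encoding.** Each CDR3 (length 11–20, canonical alphabet, conventionally
   starting with C and ending with F) is mapped to a 20 × 15 matrix: row *i*
   is the 15-dimensional biochemical-feature vector of residue *i*, obtained
   from a PCA of amino-acid property scales (below); rows beyond the true
   length are zero (post-padding).
2. **Multi-scale convolution.** 1D kernels of heights 2, 3, 4 and 5 spanning
   the full encoding width, 4 filters per height, ReLU. A height-*k* kernel
   is a detector for *k*-mer motifs; the multi-scale bank covers the typical
   length range of antigen-recognition motifs.
3. **k-max pooling** (k = 3) per filter keeps the three largest activations
   of each feature map *in their original order*, converting variable
   evidence positions into a fixed-length summary while retaining relative
   position information. Each kernel height yields a 3 × 4 block.
4. **Multi-head self-attention** (2 heads, model dimension 4, learned Q/K/V
   projections) re-weights the three pooled positions within each block.
   Per-head attention rows are softmax-normalised (they sum to one).
5. **Channel concatenation** of the four blocks gives a 3 × 16 sequence.
6. **BiLSTM** (hidden size 8 per direction) consumes that sequence; per-step
   outputs are the concatenated forward/backward hidden states (width 16).
7. **Classifier head.** Flatten (48) → fully connected layer of 6 ReLU units
   with dropout 0.5 at training time → linear layer → softmax over
   {non-cancer, cancer}. The cancer-class probability is the sequence score
   f(TCR).

Ablation flags (`use_mhsa=False`, `use_bilstm=False`) bypass stages 4 and/or
6 as identity pass-throughs; all tensor interfaces are preserved (the
flattened width is 48 in both wirings).

One wiring point was genuinely open: the architecture summary table gives the
BiLSTM an "input dimension 3" while the attention blocks are 3 × 4. We read
the 3 as the *sequence length* (the three pooled positions) and feed the
BiLSTM the 16 concatenated channels per step — the only reading consistent
with both the channel-concatenation description and the table. A second
open point is whether attention is applied per kernel-height block or once
over the concatenated blocks; we attend per block (each block is the natural
"sequence" of pooled positions for one motif length). The value projection
W_V is included by default; `value_projection=False` applies the attention
weights to the head-split inputs directly, the variant in which the
attention equations weight the feature matrix itself.

The network, its gradients (a compact reverse-mode autodiff tape over
numpy), and the Adam optimizer are implemented in this package; gradient
correctness is established against central finite differences, and each
stage against an independent brute-force oracle (explicit sliding-window
loops, per-head double loops, hand-rolled gate recurrences).

## Residue encoding

Amino-acid property scales (AAindex-style: one real value per canonical
residue per scale) are standardised to zero mean and unit variance across
the 20 residues; scales with any missing residue value are dropped. With
residues as observations, PCA reduces the scales to 15 coordinates per
residue. Signs are fixed by flipping each component so its
largest-magnitude loading is positive, making the projection deterministic.
The package reads the AAindex1 flat-file format (`deepcatcr build-encoding
<aaindex1> <out.tsv>`), so a projection can be built from the real database.

The *shipped* default projection is built from a **synthetic** table of 553
scales (fixed seed), generated from a latent-factor model: each scale is a
random mixture of 8 latent residue factors with geometrically decaying
strengths (0.85^f) plus idiosyncratic noise (sd 0.25 on the standardised
scale). This emulates the well-documented property of real biochemical
scales — high mutual correlation, a few latent properties (hydrophobicity,
size, charge, ...) dominating — under which 15 components capture ≥ 95 % of
the variance. The factor count, decay and noise level were fixed from that
qualitative knowledge before any variance measurement. What the synthetic
table does *not* give is the real database's specific residue geometry, so
classifiers trained on the shipped projection are exchangeable with, but not
numerically identical to, ones trained on a real-AAindex projection.

## Repertoire preprocessing

Quality filters (applied in a fixed order so rejection counts are
well-defined): sequence must start with C and end with F (completeness),
contain neither `B` nor `*` (productivity), have length in [11, 20], and not
appear in an optional user-supplied list of sequences common in healthy
donors. "Clone score" for top-clone selection is the clone count/frequency;
ties are broken lexicographically. Clonal-expansion selection keeps clones
with abundance ≥ 4× the repertoire minimum.

Antigen-specific enrichment is a deliberately simple stand-in for dedicated
clustering tools: single-linkage clusters of same-length sequences whose
central region (positions 4 … L−3, 1-based) differs at ≤ 1 position;
singletons are discarded. Externally produced clusterings are accepted via
a TSV exchange format (`cluster_id`, `cdr3_aa`).

## Repertoire-level predictors

With per-sequence scores f(TCR_i) of the N retained unique sequences:
mean scorer S_R = (1/N) Σ f(TCR_i); variance scorer
V_R = (1/N) Σ (f(TCR_i) − μ_R)². The population 1/N normalisation is the
default (`ddof=1` switches to the unbiased form); sequences are unweighted
by default (`weighted=True` weights by total clone count). The variance
scorer targets the dispersion signature of early clonal expansion: a small
highly-scored subpopulation inflates V_R even when S_R barely moves.

## Synthetic data

The generator emulates: CDR3 grammar (C…F, lengths 11–20 with a peaked
distribution), an 18-letter interior background (C and F present at 1 %
each), planted k-mer motifs as class signal, heavy-tailed (Pareto, α = 2)
clone counts, and a small antigen-specific fraction per cancer donor
(`ca_fraction`, default 0.05 — large enough for desk-scale power; real
repertoires are far sparser, below 0.1 %). Negatives are rejection-sampled
to provably lack positive motifs.

Two cohort designs: **planted-fraction** (cancer donors carry `ca_fraction`
motif-bearing clones; healthy none) probes the mean scorer.
**matched-mean** probes the variance scorer's mechanism in isolation:
healthy donors carry only "ambiguous-motif" clones — a motif planted in the
training set with Bernoulli(1/2) labels, so the cross-entropy-trained model
scores it near 0.5 — while cancer donors mix strong-motif and background
clones with a per-donor fraction Uniform(q* − 0.15, q* + 0.15). The center
q* is calibrated at run time so the mixture's expected score equals the
ambiguous clones' mean score (q* = (s̄_amb − s̄_neg)/(s̄_pos − s̄_neg) on
fresh calibration draws): group means then coincide by construction and only
the dispersion separates the groups.

For synthetic cohorts the scoring preprocessing disables the similarity
clustering step (filter → top-n only): clustering enriches real repertoires
through their near-duplicate clonotypes, which the i.i.d. synthetic interior
does not produce — with clustering on, nearly every synthetic sequence would
be a singleton and samples would be unscorable. Clustering stays on by
default for real-data pipelines.

What passing these tests shows — and does not. The synthetic task
demonstrates that the architecture detects sparse variable-length motifs,
that the training loop optimises and stops correctly, and that the two
repertoire scorers behave as their formulas dictate (including the
matched-mean regime where only variance carries signal). It does not
demonstrate clinical performance: real cancer-associated TCRs are not
defined by single exact k-mers, backgrounds are not i.i.d., and the
antigen-specific fraction is an order of magnitude smaller.

## Training protocol and numerical choices

Stratified 80/20 train/validation split; Adam at learning rate 0.001;
cross-entropy loss; dropout 0.5 (inverted, training only); batch size 512
(unstated in the original protocol; exposed as a knob); at most 1000 epochs
with early stopping after 20 epochs without validation-loss improvement
(improvement = strictly lower by ≥ 1e−6); parameters restored from the
best-validation epoch. Weights use fan-in uniform initialisation from a
single run seed; all randomness (initialisation, batch order, dropout
masks, splits) derives from `random_state`, making runs bitwise
reproducible. Evaluation uses a 0.5 sequence-level threshold by default;
metric ratios with zero denominators are reported as 0 (including MCC when
any factor of its denominator vanishes). Short feature maps (possible only
with non-default padded lengths) are zero-padded before k-max pooling.
5-fold stratified cross-validation re-initialises each fold independently
(fold seed = run seed + fold index) and reports mean ± sd per metric.

## Problem sizes used in the validation experiments

Cross-validated discrimination uses 2,000 + 2,000 sequences (the published
training corpus is ~30,000 + 60,000; the planted-motif task is separable at
this scale, which is the property under test). Cohort experiments use
20 + 20 donors × 300 clones; motif recovery uses 50 positive test
sequences; the reference model trains on 2,000 + 2,000 + 1,000 (ambiguous)
sequences. These sizes are the package's chosen study conditions for
desk-scale validation.

## Known limitations

* No pre-trained clinical weights are shipped; the shipped projection is
  synthetic-derived (see above), and real-data use should rebuild it from
  AAindex1.
* The clustering stand-in is much cruder than dedicated antigen-specificity
  clustering; it exists to make the preprocessing chain executable
  end-to-end, not to reproduce such tools.
* Occlusion-based motif importance is one of several plausible attribution
  mechanisms (attention weights and gradient saliency being alternatives);
  it was chosen for model-agnosticism and testability.
* The training loop is plain numpy on CPU; it is sized for the small
  published architecture, not for large-scale hyperparameter searches.
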