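# Methods

## Problem and model

Given a DNA consensus sequence, the package predicts which of C TE
classes generated it (default: the sixteen Wicker superfamilies, with a
shipped superfamily→order roll-up). The classifier is an encoder-only
transformer over k-mer tokens:

1. **Sanitation.** Input is uppercased and every non-ACGT character
   becomes N; the model alphabet is exactly {A,C,G,T,N}.
2. **Tokenization.** Overlapping k-mers (default k = 5, vocabulary
   5ᵏ = 3125 plus PAD/CLS/UNK) are taken every `step` nucleotides with
   `step = clamp(⌈len/max_embeddings⌉, 2, k−1)`. The lower bound keeps
   the default two-nucleotide stride; the upper bound k−1 guarantees
   consecutive tokens overlap by at least one nucleotide. Streams
   longer than the budget are split into consecutive non-overlapping
   CLS-prefixed chunks of at most `max_embeddings − 1` k-mer tokens.
3. **Encoder.** Token embeddings plus sinusoidal positional encodings
   (standard sin/cos form; values in [−1, 1]) pass through
   `num_hidden_layers` post-norm layers (multi-head attention →
   add&norm → GELU feed-forward → add&norm). Attention is *sparse*:
   position i attends to j only when |i−j| ≤ window/2, except that
   designated global positions attend to and are attended by everyone.
   CLS (position 0) is always global; global positions are counted in
   the CLS-prefixed coordinate system. Self-attention to one's own
   position is never masked, so no row of the attention matrix is
   empty even under padding.
4. **Head.** The final CLS vector feeds one linear layer of C outputs;
   Softmax (max-shifted) yields class probabilities. For chunked
   sequences the per-class probabilities are the element-wise median
   over chunks, renormalized to sum to one (medians of distributions
   need not be distributions). Argmax ties break to the first class in
   registry order. A sequence counts as *classified* only if its top
   probability reaches the threshold (default 0.7; 0.9 strict).
5. **Attention roll-back.** Per-token attention can be mapped back to
   nucleotide resolution by anchoring each token's value at its
   midpoint and linearly interpolating, preserving total mass — useful
   for inspecting which sequence regions drive a call.

## Training

Weighted cross-entropy `−w_y log p_y` with inverse-frequency weights
`w_c = N/(C·n_c)`, rescaled to mean 1 so the learning rate does not
depend on the weight scale; batch loss is the weight-normalized mean.
Optimizer: AdamW (β = 0.9/0.999, weight decay 0.01 on matrices only)
with linear warmup over the first 5 % of steps, then a constant rate.
The package default learning rate is 1e−4; the desk-scale experiments
below use 1e−3, the standard region for small transformers trained
from scratch, set in their own `TrainConfig`.

Augmentation (training only; inference never augments) applies ten
string edits in a fixed order — SNP, masking, insertion, deletion,
segment repeat, reverse, complement, reverse complement, poly-A
addition, poly-A removal — each with its own probability. Defaults:
0.05 for each mutating/tail kind and 0.25 for each strand kind, the
three strand kinds forming one mutually exclusive draw
(`strand_exclusive=False` switches to independent in-order
application, under which reverse∘complement composes to the reverse
complement). Magnitudes are length-relative: SNP/mask counts uniform
in [1, len/100], indel/repeat segments uniform in [1, len/20], poly-A
tails 5–30 nt. These rates are deliberately mild so the class signal
survives; all are config keys.

Each epoch re-augments and re-tokenizes the training split; every
chunk of a sequence is one training example with the source label.
Validation runs every epoch on unaugmented sequences with chunk-median
aggregation; a checkpoint (weights + optimizer moments + config
fingerprint + history) is written per epoch, and the best
validation-weighted-F1 epoch is tagged `best`. All per-epoch
randomness (shuffling, augmentation, dropout) derives from
`(seed, epoch)`, so resuming from the epoch-e checkpoint reproduces an
uninterrupted run bit-for-bit; per-epoch metrics use the validation
split, final reports the test split.

Dataset splits are stratified per class: with N_c members, train gets
⌊0.75·N_c⌋, validation gets round-half-up(0.15·N_c), test the
remainder — the convention that reproduces published per-class
partition tables — with a seeded within-class shuffle.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| kmer_size | 5 | token length, nt |
| max_embeddings | 2048 | tokens per chunk incl. CLS |
| num_hidden_layers / heads | 8 / 8 | encoder depth / heads per layer |
| embedding_dim | 256 | model width (paper-silent; chosen, configurable) |
| intermediate_size | 3078 | feed-forward width (kept verbatim from the published configuration) |
| local_attention_window | 256 | full band width w; half-width w/2 |
| global_att_tokens | [0, 256, 512] | global positions, CLS-prefixed coords |
| num_epochs | 100 | full-scale training length |
| threshold | 0.7 | minimum top probability to classify |

## Numerical engine

No GPU framework is used: parameters are float32 NumPy arrays under a
small reverse-mode autodiff (broadcasting arithmetic, batched matmul,
embedding gather, fused layer-norm / masked-softmax / GELU /
cross-entropy). Gradients are validated against central finite
differences in the test suite (float64, rel. tol 5e−3). The sparse
mask is materialized densely — at desk scale sparsity is a modelling
statement (which weights are exactly zero, asserted in tests), not a
memory optimization. Attention logits are masked additively with −1e9;
softmax is max-shifted. Initialization is truncated normal (σ = 0.02,
clipped at 2σ), seeded, bit-reproducible.

## Synthetic families

`synth` generates labeled families from a consensus drawn from a
family-specific base composition with planted motifs (internal
signatures, LTR-like terminal repeats, TIR-like inverted terminal
repeats, poly-A suffixes); copies add per-site substitutions
(each hit site redrawn to a different base) and short indel events
(per-site initiation probability, segments 1–10 nt). The consensus
stream is seeded by the spec's *generative content*, the copy stream
by its *name* — so two specs identical except for the label share one
consensus and form a genuine negative control.

The four-family preset (LTR-like 600–1500 nt GC-shifted with terminal
repeats; LINE-like 800–1500 nt AT-rich poly-A; SINE-like 300–500 nt
poly-A; TIR-like 300–700 nt with inverted terminal repeats; 200
copies/family, substitution rate 0.05, indel rate 0.002) emulates the
features the classifier exploits — composition, length structure,
diagnostic motifs, copy divergence. It does **not** emulate
phylogenetic structure, ORFs, nested insertions, fragmentation or
database label noise, so passing the recovery experiment shows the
pipeline learns and generalizes planted family signal, not that it
matches full-scale performance on curated TE databases.

Desk-scale experiment sizes (chosen so the whole suite runs on one
CPU): recovery uses the four-family preset with a 2-layer, 2-head,
width-32 model, max_embeddings 256, 30 epochs, batch 32, lr 1e−3,
seeded; the negative control trains the same architecture for 10
epochs on the identical-family pair (chance-level separability does
not improve with longer training).

## Design choices on open points

- The dynamic-step rule is implemented as `clamp(⌈len/max⌉, 2, k−1)`:
  the unique reading consistent with a minimum step of two, retained
  overlap, and the k=5/step=2 default.
- Sinusoidal encodings use the standard [−1, 1] form.
- Chunks do not overlap; chunking (not truncation) is the default for
  long inputs, with median aggregation.
- Median-aggregated probability vectors are renormalized.
- Degenerate 0/0 metric ratios report 0 (with a warning for
  zero-support classes); rounding to 2 d.p. happens only in the
  human-readable table.
- Model selection tags the best validation-weighted-F1 checkpoint;
  per-epoch metrics are validation, final reports are test.
- Softmasked (lowercase) input is uppercased, not masked.
- The trainer is exposed statsmodels-style (`TEClassifier.fit()` →
  `TrainingResults` with `summary()`, `evaluate()`, checkpoint I/O);
  the remaining modules are plain functions plus small dataclasses.

## Known limitations

- Dense materialization of the sparse mask caps practical chunk
  lengths well below what a custom banded kernel would allow.
- No pretraining objective; the classifier trains from scratch.
- No uncertainty quantification on metrics (no bootstrap CIs).
- The synthetic generator's separability is optimistic relative to
  real decayed TE libraries; real-data performance must be established
  on real labeled data.
- Training at published full-database scale (~10⁶ sequences, 8×8
  model, 2048-token chunks) is out of reach of the NumPy engine; the
  architecture supports it, the speed does not.
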