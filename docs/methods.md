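# Methods

## Overview

`rnnbias` estimates and removes sequence-specific bias from RNA-seq gene
expression. The bias model is discriminative only in effect: two generative
character-level language models are fit — one to context windows centered on
observed read 5'-end positions (foreground), one to windows at small random
offsets of those positions (background) — and each counted site is assigned
the likelihood ratio of its window under the two models. Counts are divided
by the ratio before FPKM normalization. The approach assumes the bias acts
through the local nucleotide context of the read start (the random-priming
mechanism), that nearby offset positions are an unbiased sample of the same
local base composition, and that the bias is shared across the genome (one
model pair per library, not per gene).

## Coordinate and orientation conventions

All coordinates are 0-based, half-open. SAM input (1-based) is converted on
read; BED12 is natively 0-based. A read's "start" is the 5' end of the
aligned sequence: the leftmost aligned reference base for forward-strand
alignments, the rightmost (computed from the CIGAR reference span) for
reverse-strand ones. Both mates of a pair contribute a site by default
(each cDNA synthesis event is primed independently); `read1_only` restricts
to first mates. Context windows of minus-strand sites are
reverse-complemented so every model sees the priming-proximal orientation.
Uniquely mapped means `NH == 1` when the tag is present, else mapping
quality at or above `min_mapq` (default 255, the common splice-aligner
convention for unique alignments).

## Language models

Sequences over {A,C,G,T} (fixed one-hot order A<C<G<T) are scored by the
chain rule with conditionals from a single recurrent layer:

- vanilla: `h_t = tanh(W s_t + U h_{t-1} + b)`
- GRU: update/reset gates and candidate, `h_t = (1-z)⊙h̃ + z⊙h_{t-1}`,
  with the reset gate applied to the previous state before the recurrent
  matrix (`h̃ = tanh(W s + U (r⊙h) + b + d)`)
- LSTM: input/forget/output gates, cell state, `h_t = o ⊙ tanh(c_t)`
- output: `softmax(V h_t + c)`

Gated units carry both an input-side (`b`) and a recurrent-side (`d`) bias
per gate; the vanilla unit has a single bias. This is the convention under
which the standard parameter totals hold exactly (GRU-10: 524, GRU-20:
1644, LSTM-10: 684, LSTM-20: 2164), and it matches the common
char-RNN/cuDNN layout. The first conditional p(s₁) comes from a zero
initial state driven by an all-zero input vector, which keeps the input
dimension at 4 and adds no parameters.

Training minimizes mean per-symbol negative log-likelihood by mini-batch
gradient descent with backpropagation through time over full fixed-length
sequences and element-wise gradient clipping. Defaults: uniform(-0.08,
0.08) weight init with zero biases, learning rate 0.1, batch 50, clip 5.0,
30 epochs, plain SGD. An Adam optimizer (lr 0.01 recommended) is also
provided and converges roughly an order of magnitude faster on these small
models; the integration tests and the reproduction script use it so they
can run at small epoch counts. The returned parameters are those of the
epoch with the lowest validation prediction-error rate (fraction of
positions where the argmax conditional misses the observed symbol), ties
to the earliest epoch. Perplexity is per-symbol: 2 to the mean negative
log₂ conditional probability, so 4.0 is chance level on a 4-letter
alphabet.

Numerical choices: log-softmax uses max-subtraction; all arithmetic is
float64; analytic BPTT gradients are verified against central finite
differences (step 1e-5) with the relative-error denominator floored at
1e-6, so near-zero components are compared absolutely — a ratio of
finite-difference roundoff (~1e-11) to a ~1e-8 gradient is measurement
noise, not a derivative mismatch. Model files are JSON with full-precision
float round-trip (Python repr), so save/load is bit-exact.

## Sampling

Exonic read-start counts are formed by intersecting sites with the merged
exon intervals of all genes (position only; site strand is not matched to
gene strand, since priming bias is strand-symmetric in the window
orientation convention above). Foreground sites are drawn with replacement
with probability proportional to read count — sampling reads, not
positions, so frequent starts dominate the foreground model as they
dominate the bias. Background sites shift each foreground site by a
non-zero offset uniform on ±{1..30}; small offsets keep the background in
the same genomic neighbourhood, controlling for composition. Windows that
would leave the contig or contain an N are filtered (the boundary filter);
both classes of sequence are exactly 2w+1 long, 21 bp at the default
w = 10 (41 bp at w = 20). The 100 k-per-model default and the 90:5:5
shuffle-then-split (train/validation sizes rounded, remainder to test) are
the method's standard operating point.

## Quantification and evaluation

Raw FPKM is `1e9 · Σᵢ nᵢ / (L_g · N)` over the gene's exonic read-start
positions, with N the total counted reads. Correction replaces nᵢ by
nᵢ/biasᵢ and keeps the same denominator N — no renormalization by the
reweighted total, as the formula is written. Sites whose window is
undefined keep weight 1.0 and are flagged. Positions inside several genes'
exons count toward each. Correlation metrics drop pairs where either value
is ≤ 0, compute Pearson on log₁₀ of both (base immaterial to r), Spearman
on the raw filtered values, and r² as the squared log-Pearson. The
expression shift between raw and corrected estimates is summarized by
per-gene `log₁₀((corrected+ε)/(raw+ε))` (ε = 1e-6) as a root-mean-square
"Euclidean" distance — RMS makes the value independent of gene count —
plus counts of increased/decreased genes.

## The simulator

The generator emulates exactly the mechanism the method targets: read
starts whose selection probability depends on local context through a
known log-linear PWM over the 2w+1 window, `weight(p) = exp(Σⱼ M[j,
base(p-w+j)])`. A dataset is an i.i.d.-uniform genome (default 100 kb),
non-overlapping two-exon genes (200 bp exons, default 100 genes) placed
with margin ≥ w from contig ends, log-normal(0, 1) relative abundances,
and 200 k reads. Under the default `per_site` scheme a read lands at
exonic position p of gene g with globally-normalized intensity ∝
(abundance_g / exonic_length_g) · weight(p): per-base transcript abundance
times priming efficiency. Gene totals are then distorted by each gene's
mean context weight — the distortion the pipeline must remove. The
alternative `per_gene` scheme assigns reads to genes by abundance first
and only then picks positions by weight; it leaves gene totals exactly
multinomial in the true abundances (raw FPKM unbiased), which isolates
site-level behaviour but gives the correction nothing to fix at the gene
level. `random_pwm(w, scale)` draws a row-centered uniform(±scale) matrix;
scale = ln 3 is the "strong bias" condition used in the end-to-end tests.

What the simulator does not emulate: fragment-length distributions,
sequencing errors, PCR duplicates, positional (5'→3') bias along
transcripts, reverse-strand reads (strand handling is exercised by its own
unit tests), alternative isoforms, and non-uniform genome composition.
Passing the end-to-end tests therefore shows the estimator recovers a
context-driven read-start bias of the assumed log-linear form under clean
conditions; it does not certify performance on real libraries, where the
bias is milder but the nuisance structure is richer.

## Problem sizes and a noise-amplification caveat

The end-to-end checks run the full pipeline (count → sample → train GRU-10
foreground and background → weight → quantify) on the default simulated
conditions with 4000 sampled sequences per model and 3 Adam epochs —
deliberately light training that finishes in seconds per seed. A finding
worth recording: under the very strong simulated bias (per-site weights
spanning several e-folds), heavier training (20 k sequences, 8 epochs)
makes the learned log-ratio track the true log-weight *better* (r ≈ 0.82,
slope ≈ 1.05 versus r ≈ 0.63, slope ≈ 0.60) yet yields *worse* corrected
expression, because dividing small counts by accurately small weights
amplifies shot noise at rarely-primed sites — only sites with at least one
read enter the table, so 1/weight outliers are not averaged away. The
shrunken ratios of the lighter fit act as implicit regularization, echoing
the method's own preference for lightweight models on foreground data.
The optional symmetric clip on the ratio (`clip`, off by default to match
the plain formula) is the explicit guard when heavier training is wanted.

## Known limitations

- Single recurrent layer only; no dropout, no variable-length batching.
- The trainer holds the encoded training set in memory (fine for the
  100 k × 21 operating point).
- The bias ratio is estimated per site from one window; no smoothing or
  joint estimation with abundance (Cufflinks-style) is attempted.
- BED12 is the only gene-model dialect; isoform-level quantification and
  TPM are out of scope.
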