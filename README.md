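# rnnbias

Sequence-specific bias correction for RNA-seq expression estimates using
character-level recurrent nucleotide language models.

## The problem

During cDNA library preparation, random primers bind RNA with efficiencies
that depend on the local nucleotide sequence. The probability that a read
starts at a given position therefore depends on the genomic context around
its 5' end, which distorts read counts and, through them, gene expression
estimates. The classical remedies model the context windows around observed
read starts (foreground) versus nearby offset positions (background) with
hand-specified structures — positional heptamer ratios, variable-length
Markov models, or Bayesian networks with learned topologies. This package
takes the language-modelling route instead: a small recurrent network learns
whatever sequential dependency structure the data contains, with no
pre-determined topology.

## The model

Each context window S = s₁s₂…sₘ (2w+1 nucleotides centered on a read 5'
end, m = 21 by default) is scored by the chain rule

  p(S) = p(s₁) ∏ₜ p(sₜ | s₁…sₜ₋₁),

with each conditional read off a softmax over a recurrent hidden state:

  hₜ = tanh(W sₜ + U hₜ₋₁ + b)      (vanilla RNN)
  yₜ = softmax(V hₜ + c)

and GRU / LSTM gating variants of the recurrence to ease training (each
gate carries an input-side and a recurrent-side bias, so GRU-10 has 524
parameters, GRU-20 1644, LSTM-10 684, LSTM-20 2164). Two models are trained
by backpropagation through time: a foreground model on windows sampled at
observed read starts (in proportion to read count) and a background model
on windows at random offsets of those sites. A site's bias weight is the
probability ratio

  bias(r) = p_f(contextSeq(loci(r))) / p_b(contextSeq(loci(r))),

and bias-corrected expression divides each position's read count by its
weight inside the FPKM sum:

  FPKM(gene) = 10⁹ · Σᵢ nᵢ / biasᵢ / (length(gene) · N),

with N the total number of counted reads. Everything — the three recurrent
cells, BPTT gradients, training loop, perplexity and model selection by
validation prediction-error rate — is implemented from first principles in
NumPy and verified against enumeration and finite-difference oracles.

A synthetic-data generator completes the package: genomes, gene models,
log-normal abundances and read starts drawn with a *known* injected
log-linear positional-weight-matrix (PWM) bias, so the whole pipeline is
testable end to end without any external data.

## Worked example

```python
import math
from scipy.stats import spearmanr
import rnnbias as rb

pwm = rb.random_pwm(w=10, scale=math.log(3), seed=42)     # known injected bias
sim = rb.simulate_dataset(rb.SimConfig(pwm=pwm, seed=7))  # 100 genes, 200k reads
run = rb.correct_simulated(sim, n_sequences=4000, seed=7,
                           epochs=3, optimizer="adam", learning_rate=0.01)

print(run.fg_results.summary())
truth = run.expression["abundance"]
for col in ("raw_fpkm", "corrected_fpkm"):
    m = rb.correlation_metrics(run.expression[col], truth)
    rho = spearmanr(run.expression[col], truth).statistic
    print(f"{col:15s} pearson_log={m['pearson_log']:.4f} spearman={rho:.4f} r2={m['r2']:.4f}")
```

prints

```
Nucleotide RNN language model
============================================
unit:            gru
hidden units:    10
parameters:      524
epochs run:      3
selected epoch:  3
train NLL/sym:   1.365857
valid NLL/sym:   1.356183
valid err rate:  0.662143
raw_fpkm        pearson_log=0.9525 spearman=0.9468 r2=0.9072
corrected_fpkm  pearson_log=0.9702 spearman=0.9718 r2=0.9413
```

The foreground GRU (524 parameters) has learned the injected priming
signal — its per-symbol NLL is well below the ln 4 ≈ 1.386 of featureless
sequence — and dividing counts by the learned probability ratios moves the
expression estimates closer to the simulated truth on every metric.

The same pipeline is available from the shell:

```bash
rnnbias simulate --out sim --pwm-scale 1.1 --seed 7
rnnbias sample   --genome sim/genome.fa --genes sim/genes.bed \
                 --reads sim/read_starts.tsv --out seqs --n 4000 --seed 7
rnnbias train    --train seqs/fg_train.txt --valid seqs/fg_valid.txt \
                 --optimizer adam --lr 0.01 --epochs 3 --out fg.json --seed 7
rnnbias train    --train seqs/bg_train.txt --valid seqs/bg_valid.txt \
                 --optimizer adam --lr 0.01 --epochs 3 --out bg.json --seed 7
rnnbias bias     --fg fg.json --bg bg.json --genome sim/genome.fa \
                 --genes sim/genes.bed --reads sim/read_starts.tsv --out bias.tsv
rnnbias quantify --reads sim/read_starts.tsv --genes sim/genes.bed \
                 --bias bias.tsv --out expr.tsv
rnnbias evaluate --expression expr.tsv --ref sim/truth_genes.tsv --out metrics.json
```

## Layout

| module                | contents |
|-----------------------|----------|
| `rnnbias.genome_io`   | FASTA / BED12 / SAM / read-start-TSV readers, strand-aware context windows |
| `rnnbias.sampling`    | exonic read-start counting, foreground/background sampling, train/valid/test split |
| `rnnbias.rnnlm`       | `NucleotideRNN` model and `RNNResults` — RNN/GRU/LSTM cells, BPTT, perplexity, serialization |
| `rnnbias.bias`        | probability-ratio bias weights and the per-site bias table |
| `rnnbias.quantify`    | FPKM with/without reweighting, correlation metrics, expression-shift diagnostics |
| `rnnbias.simulate`    | synthetic genomes/genes/reads with a known injected PWM bias |
| `rnnbias.pipeline`    | one-call end-to-end driver for simulated data |
| `rnnbias.cli`         | `rnnbias` subcommands wrapping all of the above |
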