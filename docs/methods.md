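# Methods

## Column profiles

An alignment column is reduced to the 20-vector of canonical amino-acid
fractions. Two conventions needed fixing:

* **Coverage filter.** A column is dropped when the 20 canonical residues
  account for less than 75% of all rows (gaps `-`/`.` and ambiguity codes
  B, Z, X, U, O count in the denominator). The comparison is strict, so a
  column at exactly 75% survives. The threshold is configurable
  (`--min-canonical`).
* **Renormalization.** Surviving columns renormalize over canonical
  residues only, so `Σ pᵢ = 1` exactly. This is required for the
  reconstruction objective: binary cross-entropy against a sigmoid output
  needs targets in [0, 1] with a well-defined optimum at `r = p`. Whether
  gap-containing denominators were used upstream of published EV analyses
  is not knowable from the fraction vectors alone; renormalizing is the
  only choice that keeps the loss well-posed.

In **sorted mode** fractions are ordered high-to-low (stable sort; ties
keep alphabet order), so the model sees only the variability pattern. In
**fixed-order mode** position i is always the fraction of
`ACDEFGHIKLMNPQRSTVWY[i]`, so residue identity is modeled; the 20 one-hot
"pure" columns then map each amino acid into the latent plane
(`fixed_order_summary`).

## EV statistics

Entropy is `−Σ p ln p` in nats (`0·ln 0 := 0`; other log bases are an
output option and cancel in the normalization). Variability counts types
with fraction strictly above a floor (default 0; real alignments may want
a small noise floor against sequencing artifacts). Normalized entropy is
`H / ln v`, defined as 0 at `v = 1`. The five-box classifier bins
`(variability band, normalized-entropy band)` with two cuts per axis
(defaults: v cuts 2 and 9, entropy cuts 0.33 and 0.67; lower-edge
inclusive, so a value on a cut joins the higher band). The diagonal cells
map to boxes 11, 12, 22, 23, 33; off-diagonal cells return `"other"`
rather than being forced into a neighbour, because the box boundaries are
guidelines, not sharp classes — the defaults here are placeholders and
every cut is configurable.

## Autoencoder

Architecture: encoder 20-15-10-5-2 (configurable, e.g. 20-16-8-4-2 or a
3-unit bottleneck), symmetric decoder, independent (untied) weights. Every
hidden layer, the bottleneck included, is affine → batch normalization →
sigmoid; the 20-unit output layer is affine → sigmoid without
normalization, since it is not a hidden layer. Training: greedy layerwise
pretraining — stage k trains the (encoder k, mirrored decoder) pair as a
shallow autoencoder on the inference-mode codes of depth k−1, so each
stage's targets are sigmoid outputs in (0, 1) and BCE stays well-defined —
followed by end-to-end fine-tuning of all parameters. Optimizer: Adam,
learning rate 1e-3, batch size 128, β = (0.9, 0.999), ε = 1e-8.

Numerical choices:

* Mean (per element, per row) BCE with reconstructions clamped to
  `[1e-7, 1−1e-7]`; the gradient at the output uses the exact
  sigmoid-BCE form `(r − t)/N`.
* Batch-norm ε = 1e-5, running-statistics momentum 0.1; training uses
  batch statistics, inference uses frozen running statistics — this is
  what makes `encode` deterministic and batch-size independent.
* Weight init: uniform ±1/√fan-in from the run seed; per-epoch shuffling
  from a seed stream derived from the same run seed. Two runs with the
  same seed and data order produce identical parameters.
* Epoch defaults: 20 pretraining epochs per layer, 50 fine-tuning epochs —
  at the 50k-column scale the fine-tuning loss is flat well before epoch
  50 (final training BCE ≈ 0.114, within 3% of the assembled pretrained
  stack's starting point).
* No validation split or early stopping; callers hold out data before
  training when they need an untouched evaluation set (the acceptance
  script holds out 5,000 of 50,000 columns).

Models serialize to a self-describing JSON file (format version, config
snapshot, parameters, normalization statistics, loss history); floats
round-trip exactly, so a saved and reloaded model encodes bit-for-bit
identically.

## Synthetic corpus

Each column draws its variability v from a weight vector over 1..20, picks
v types uniformly at random, and draws their fractions from a symmetric
Dirichlet(α). Support size and concentration independently control
variability and evenness — precisely the two axes under study. Defaults:
50,000 columns, v uniform over 1..14 (the range seen in deep MSA corpora),
α = 1.0, seed 42. Alignment emission samples each column multinomially
(default 100 sequences) and then overwrites positions with gaps or
non-canonical codes at configurable rates, which exercises the coverage
filter end to end.

What the generator does **not** emulate: phylogenetic correlation between
columns and sequences, alignment errors, the skewed occupancy of real MSA
columns (real columns are typically dominated by one or two residues — a
Dirichlet with α well below 1), or any database-specific weighting.
Passing tests on this corpus therefore validate the machinery and the
qualitative claims, not distributional agreement with real proteomes.

## Latent-axis matching and a known limitation

`match_axes` computes the Spearman rank correlation of each bottleneck
neuron against normalized entropy and variability (rank correlation is
invariant to the sigmoid's monotone warping; ties get the standard
correction), then picks the injective neuron→statistic assignment
maximizing Σ|ρ| by exhaustive enumeration. The operational threshold used
in the acceptance suite — both matched |ρ| ≥ 0.8 — is this package's
quantification of "the learned features strongly resemble entropy and
variability". `low_variability_separation` is the silhouette score of the
{v ≤ 2} versus {v ≥ 3} partition in latent space; trained models place the
conserved and two-type columns as distinct groups in a corner of the
neural plot, giving clearly positive scores (≈ 0.4–0.6 at the default
scale).

**Limitation — axis orientation is not identified on flat corpora.** On
the default α = 1.0 corpus, training reliably reaches the reconstruction
floor and the 2-D latent plane *jointly* contains both statistics (a k-NN
readout recovers normalized entropy at ρ ≈ 0.88 and variability at
ρ ≈ 0.98), but the reconstruction objective does not pin the *rotation* of
the code: across seeds and architectures one neuron tracks the dominant
entropy/variability continuum strongly (|ρ| ≈ 0.87–0.97) while the
per-neuron correlation of the evenness axis wanders between ≈ 0.3 and 0.7.
With a skewed, more realistic occupancy (α = 0.3) the same pipeline yields
axis-aligned neurons (matched |ρ| ≈ 0.82 and 0.88): the disentanglement
into entropy-like and variability-like neurons emerges from the data
distribution, not from the architecture alone. The acceptance suite keeps
the α = 1.0 conditions and asserts the 0.8 threshold as defined, so the
two assertions that depend on per-neuron alignment fail there by design of
the conditions; the diagnostic evidence above is the honest reading of
that outcome.

## 3-D bottlenecks

A 3-unit bottleneck is supported (`--layers 20,15,10,5,3`;
`match_axes` scores all six injective assignments). No interpretation is
attached to the third neuron: no analysis here or elsewhere has related it
to a meaningful third column statistic.

## Problem sizes

Defaults were chosen so a full pipeline — corpus generation, EV table,
pretraining, fine-tuning, matching — completes in a few minutes on one CPU
core: 50,000 columns × (4 × 20 pretraining + 50 fine-tuning) epochs at
batch 128. The test suite trains smaller models (hundreds to a few
thousand columns) except for the acceptance tests, which run the full
default conditions.
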