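# Methods

## The prediction problem and the mutant-priority decomposition

A mutation-based synthetic promoter library consists of a base promoter
S = (x₁, …, xₙ) and variants S′ that differ from it at a few substitution
sites, each labelled with a log-scale strength (log Fluorescence/OD600).
The decomposition step aligns S′ to S, collects the mutation sites
{i : xᵢ ≠ x′ᵢ}, and cuts the k-length window of S′ centred on each site
(indices i − ⌊k/2⌋ … i + k − ⌊k/2⌋ − 1, 0-based; left-heavy for even k;
indices outside the sequence read as the blank character `B`).  The pair
⟨S, windows⟩ is equivalent to S′: `reconstruct` overlays the windows on S
and must reproduce S′ exactly.  This equivalence is the central invariant
of the package and is property-tested for every window size.

Sequences live over the closed five-letter alphabet (A, T, C, G, B) with a
fixed channel order, one-hot encoded with d = 5.  `B` triples as padding
(every library is right-padded to a fixed length L, default 85), alignment
gap rendering, and masking.  Alignment uses Needleman–Wunsch
(match 1, mismatch −1, gap −2, ties broken diagonal → up → left); for
substitution-only pairs of equal length the aligner reduces to the
identity.  Gaps are rendered as `B` so indels stay expressible in the
one-hot alphabet; positions are then fixed in the aligned, padded
coordinate system.  How a real library's indels were coordinatised by the
original GUI-based alignment is unknowable from the outside; the
B-rendering convention here is a package choice and is exercised by an
indel-generation flag in the simulator.

The window-size heuristic `suggest_k` returns round(l/α) (floored at 1),
where l is the promoter length and α the mean mutation count — large
enough for context, small enough that windows of the α typical sites do
not overlap excessively.

## Mutation representations

**Vars+PE** stacks the windows as one-hot rows in a fixed-shape tensor of
k·max_sites rows × 5 columns (site blocks in ascending position order,
unused trailing blocks zero; max_sites defaults to 18, comfortably above
the ≤8 sites that dominate mutant libraries even when augmentation against
distant bases raises the count).  Every one of the k rows of a block
receives the *same* sinusoidal positional encoding PE(p) of its mutation
site p — the windows alone lose base order, so PE carries all positional
information.  PE is the standard alternating sin/cos ladder
(`PE(p)[2i] = sin(p / 10000^{2i/d})`, odd channels cos; odd widths end on
a sin channel).

**Mask** keeps the variant at full length L but blanks every position
outside all windows to `B`.  Base order is preserved, so no PE is needed.
Classical regressors consume the concatenation of the flattened base
one-hot and the flattened Mask (2·L·5 features).

## Models

`EVMPRegressor` embeds the base promoter (BaseEncoder) and the mutation
set (VarEncoder) and concatenates the two embeddings into a two-layer FFN
head (hidden 64, no output activation).  The objective is
Σ|ŷ−y| + λ‖w‖²; λ (default 1e-5) is realised as decoupled weight decay for
the deep families and mapped to each classical family's native L2 analog
(xgboost `reg_lambda`; RF/GBDT have no L2 analog and SVR keeps its native
C, so λ is ignored there).  Labels are internally standardised for the
deep families and de-standardised at prediction.

Deep families (`lstm`, `transformer`) run on an in-package numpy
reverse-mode autodiff engine (`evmp.nn`): dense layers, a fused
backprop-through-time LSTM, pre-norm transformer blocks, Adam.  Training
is minibatch L1 with early stopping on validation MAE (defaults: hidden
width 32, 2 transformer layers / 4 heads, batch 128, learning rate 1e-2,
≤60 epochs, patience 10) and is bit-reproducible for a fixed seed on a
fixed thread count.  Classical families (`rf`, `gbdt`, `xgboost`, `svm`)
wrap scikit-learn/xgboost regressors over the Mask-based flat features
with a single shared model, as the paired-stream structure has no meaning
for them.

Two input-pipeline choices for the deep VarEncoder deserve explanation,
because the naive alternatives silently fail:

* **Right-aligned site blocks.**  In the fixed-shape tensor the site
  blocks are packed against the *end* of the k·max_sites window.  An
  all-zero input prefix leaves an LSTM's state exactly zero (the candidate
  gate is tanh(0) = 0), so right-alignment emulates variable-length
  sequence packing and the final hidden state sits directly after the last
  real window.  With trailing zeros instead, the state decays through
  ~σ(1)^t ≈ 0.73^t per padding step and the encoder output collapses to a
  constant — over-smoothing introduced by the layout itself.  The
  canonical Vars+PE tensor (used for diagnostics and serialisation) keeps
  the documented leading-blocks layout; the re-packing is a model-input
  detail.
* **PE at model width** (`pe_mode="projected"`, the default).  The one-hot
  rows pass through a learned projection to the model width and the PE of
  the mutation site — computed at that width — is added *after* the
  projection.  A 5-dim PE added at the one-hot level (`pe_mode="onehot"`,
  kept as a switch) is mathematically injective over 85 positions but
  provides only two smooth channels plus two aliasing ones, which is too
  poor a position code to generalise per-position effects from; models
  trained on it memorise without generalising.  The projected variant is
  the standard transformer practice of matching PE width to model width.

`FullSequenceRegressor` is the non-EVMP baseline: the same encoder
families over the raw one-hot variant sequence (plus projected PE), same
budget, same interface.  Its "encoder" excludes the FFN head for
diagnostic accounting.

## Data augmentation

A panel of m base promoters P₁…P_m (by convention the library base is P₁,
so the single-base setting is a subset) re-expresses each variant m ways.
Modes: `fixed` (one designated base), `rand` (one uniformly drawn base per
variant, seeded), `augmented` (all m bases; exactly m·N records,
variant-major).  Records identical to their base encode as empty mutation
sets and are kept.  For augmented evaluation both the per-record metric
(primary) and the per-variant mean-aggregated metric are available, since
either accounting is defensible; `aggregate_predictions` implements both.
Splits group by variant id, so no variant can leak across train/val/test
through a different base promoter.

## Synthetic library generator

The generator emulates the statistical structure of a real mutant library:
a random 80-nt base (padded to 85), N = 2000 variants by default, mutation
counts drawn from a distribution over 1–8 with mode at 2–4 (mean α ≈ 3.1),
positions uniform without replacement, substituted bases uniform over the
three alternatives.  The ground truth is additive: per-(position, new
base) effects drawn once per seed from a zero-mean Gaussian and rescaled
so the noiseless strengths span exactly 2.0 log units (matching the
≥2-orders-of-magnitude raw-scale spread of real libraries), plus an
intercept of 3.0 and N(0, σ) measurement noise with σ = 0.1 log units —
small against the span, so representation effects remain detectable at
N = 2000.  σ implies an irreducible MAE floor of σ·√(2/π) ≈ 0.080.
Optional pairwise epistasis terms (off by default) let tests probe where
the additive surrogate breaks.  A base-promoter panel generator emits
alternative bases at Hamming distance 2–7 from the library base.

What the generator does *not* emulate: motif structure (−35/−10 boxes),
biophysical nonlinearity, indel mutagenesis (available behind the
substitution-only default but not part of the additive truth), or the
long-tailed strength distributions of real screens.  Passing tests
therefore demonstrate pipeline correctness and the representational
mechanism, not real-library accuracy.

## Evaluation protocol and diagnostics

Metrics: MAE (primary — sensitive to the absolute scale, which matters
most for strong promoters) and R² (secondary; computed against the
evaluation set's own label mean, undefined for zero-variance labels).
The split protocol holds out a fixed 1/10 test set at the variant level,
then performs five seeded 9:1 train/validation resplits of the remainder,
reported as mean ± s.d.  (A literal 5-fold scheme would imply 80/20
validation folds; the repeated 9:1 resplit matches the stated 9:1
fractions and is the interpretation implemented here.)
`data_efficiency_curve` keeps one fixed validation set while subsampling
the training pool to given fractions.

Over-smoothing is quantified by the average embedding distance
d_l = (1/N) Σ ‖e_l(Pᵢ) − e_l(P₀)‖₂ / n_l, with the zero-mutation record
(the base promoter itself) as reference P₀ and layer 0 defined as the raw
input: the flattened canonical Vars+PE tensor for the mutation stream and
the flattened one-hot for the full-sequence stream (n₀ = the flattened
dimension; for one-hot inputs with m mismatches the closed form is
mean(√(2m))/n₀, which the tests verify).  LSTM encoders report one d_l per
time step, transformers one per block; d_l is computed over the full
labelled library by default.  Classical families expose no layer
embeddings and raise an explicit unsupported-operation error.

## Numerical and degenerate-input choices

* Alignment requires non-empty sequences; `k < 1`, α ≤ 0, non-probability
  mutation-count vectors, zero-size libraries and infeasible panel bounds
  raise value errors.
* Overlapping windows must agree where they overlap; `reconstruct` raises
  a consistency error naming the first conflicting position.
* One-hot decoding is exact on one-hot input (argmax over the fixed
  channel order).
* Strengths serialise via `repr` for bit-exact read/write round trips;
  records serialise to JSON-lines.
* Deep training aborts with a divergence error (naming the epoch) on a
  non-finite loss; label standardisation falls back to scale 1 for
  zero-variance labels.
* Rounding in `suggest_k` and split sizes uses conventional half-up /
  banker's-free arithmetic (floor(x + 0.5); split sizes round the group
  counts).

## Desk-scale study sizes

The shipped study routines (`evmp.experiments`, also driven by
`scripts/acceptance.py`) use: 1000 variants × k ∈ {1,3,5,8} for the
equivalence check; 200 random pairs of length ≤12 against an exhaustive
alignment oracle; N = 2000 libraries for forest ground-truth recovery, the
five-repeat LSTM enhancement comparison (k = 3, identical architecture,
budget and seeds for both models) and the d₀ comparison; and a 10-promoter
panel over N = 2000 for augmentation accounting.  These sizes were chosen
so the full suite runs comfortably on a single desktop CPU while leaving
the measured effects well clear of their decision thresholds.

## Known limitations

* The additive ground truth makes the task linearly decodable; absolute
  MAE values here say nothing about real-library MAE.
* The deep models are deliberately small; no hyperparameter search is
  performed or supported.
* Local alignment, affine gaps and multi-sequence alignment are out of
  scope; the aligner is only exercised meaningfully when indel variants
  are generated.
* Reproducibility is promised as metric equality within 1e-6 across
  platforms (bitwise only on a fixed platform/thread count).
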