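# Methods

## The modeling problem

A protease panel (here, matrix metalloproteinases) is profiled against a
library of 10-mer peptide substrates spanning the P5…P5′ register around the
scissile bond. Each substrate–protease pair carries a normalized cleavage
Z-score Z_{s,m}: a continuous, per-protease-standardized readout of relative
cleavage strength from a high-throughput screen. The package learns this map
in both directions — sequence → profile (predictor) and profile → sequence
(conditional generator) — and supplies the score calculus used to select
substrates and to calibrate predictions against an in vitro fluorogenic
screen.

## Predictor

Multi-task regression: one input sequence, M outputs (one Ẑ per protease),
mean-squared-error loss averaged over outputs. Two backbones:

- **Transformer** (default): tokens are PAD=0, the 20 canonical residues at
  indices 1–20 (alphabetical), then CLS. Embedding dim 32, fixed sinusoidal
  positional encodings, 2 post-norm encoder blocks with 6 attention heads of
  width 5 (inner width 30, projected back to 32 — 32 is not divisible by 6,
  so head width is rounded down and the output projection restores the model
  dimension), feed-forward width 128 (4× model dim). The CLS representation
  after the last block feeds a linear head with M outputs. Learning rate
  follows the warmup/inverse-square-root schedule
  lr(t) = d⁻⁰·⁵ · min(t⁻⁰·⁵, t · w⁻¹·⁵) with Adam; batch size 64.
- **biLSTM**: 2 bidirectional layers of hidden size 32 per direction,
  dropout 0.25 after each layer, mean-pooling over non-pad positions,
  constant Adam lr 5e-3, batch size 32.

An ensemble of K = 5 members is trained over independent 80/20
train/validation resplits (member seed = master seed + member index); per
epoch the validation loss is evaluated and the best checkpoint per member is
kept. The prediction is the member mean; the uncertainty σ is the population
standard deviation across members (exactly 0 for K = 1).

Default training length is 70 epochs with a 4000-step warmup, matching the
reference configuration for screens of ~15k training sequences. For the
package's own benchmark scale (4000-peptide simulated screens, ~50
optimizer steps per epoch) those settings leave the schedule inside its
warmup for the entire run, so the benchmarks use a warmup of 500 steps and
40 epochs — the schedule's shape is unchanged, its horizon is matched to
the dataset. At this scale the transformer also overfits the readout noise
(training loss falls below the noise floor while validation loss rises), so
a standard sublayer dropout of 0.1 (after the attention and feed-forward
sublayers, training only) is enabled by default; set
`transformer_dropout=0` to disable.

Evaluation: per-protease MAE and Pearson r, plus ROC-AUC for the binary
task "Z ≥ Z_t" at thresholds {0, 1.0, 1.5, 2.0, 2.5}; thresholds that leave
a single class yield NaN with a warning.

## Generator

Decoder-only transformer: 3 causal post-norm blocks, model dim 64, 6 heads
of width 10 (inner 60, projected to 64), feed-forward 256, batch 128, the
same warmup/inverse-sqrt schedule. Sequences are wrapped in START/STOP; the
loss is next-token cross-entropy (STOP included, PAD masked). Each training
sample is conditioned with probability 0.5 (per-sample Bernoulli draw, seeded):
its own Z-row, rounded to the nearest tenth, is mapped by a learned linear
layer to the model dimension and replaces the START embedding at position 0.
A 10% slice of the input is held out to select the checkpoint with the
lowest held-out loss (using the evaluation test set for checkpointing would
leak; the slice is carved from training data instead).

Sampling is autoregressive with temperature T (logits/T) and a sign-aware
repeat penalty restricted to the immediately preceding token (positive logit
divided by the penalty, negative multiplied; 1.0 is the identity) —
defaults: T = 1, penalty 1.2 unconditionally; T = 1.2, penalty 1.2
conditionally. Generation halts at STOP or at 20 residues (then STOP is
forced). Post-hoc filtering removes off-length generations and exact matches
to the training set, and reports the counts per removal class.

## Score calculus

- Selectivity: S_{s,m} = Ẑ_{s,m} − (1/(M−1)) Σ_{i≠m} Ẑ_{s,i}. Adding δ to
  the target entry adds δ to S.
- Screen efficiencies: kinetics (substrate × protease × replicate ×
  time × fluorescence) reduce per replicate to an endpoint fold change (or a
  least-squares slope in rate mode), replicates are averaged, and cleavage
  is called against a blank-derived cutoff (mean + 3 sd of no-enzyme
  controls when present, else a fold-change floor of 1.2 — the screen's own
  call rule is a configuration point, not a claim). Per protease:
  non-cleaved → 0, the top signal → exactly 1, others →
  FC_x / (FC_max − FC_min̄) clipped to [0, 1], with FC_min̄ the mean signal
  of non-cleaved substrates (set the mode to `zero` for the plain
  FC_x/FC_max reading).
- Cleavage thresholds: per protease, the predicted-score cut maximizing
  Youden's J (sensitivity + specificity − 1) for the rule Ẑ > T, scanning
  the midpoints between adjacent sorted scores; ties resolve to the median
  of the tying candidates, which for separable data is the midpoint of the
  separating gap. "Maximizing ROC-AUC by a threshold" is not well-posed
  (AUC is threshold-free), so the operating point maximizing J is used;
  fits with J < 0.25 carry a low-confidence warning. Proteases without
  usable labels receive the mean of the fitted thresholds, flagged imputed.
- Corrected efficiency: Ê = (Ẑ − T_m)/max_s(Ẑ − T_m) when Ẑ > T_m
  (strict), else 0; columnwise max is 1 whenever any substrate clears the
  threshold. Invariant to common positive rescaling of (Ẑ − T_m) within a
  column.
- Corrected selectivity: the selectivity formula applied to Ê; bounded in
  [−1, 1].
- Quadrants: strict cuts E > 0.4 and S > 2.4 define the four activity
  classes.

## Design workflows

Efficiency nomination ranks by the uncertainty-aware score Ẑ − σ for the
target; selectivity nomination ranks by predicted selectivity without an
uncertainty adjustment. The 5-mer diversity filter is a greedy pass in
descending score order (ties broken lexicographically for determinism): a
candidate is kept iff none of its overlapping 5-mers has been claimed, and
kept candidates claim all of theirs — the output has globally unique 5-mers
and the filter is idempotent. The site-independent baseline samples each
position independently from the source set's empirical residue frequencies;
it reproduces position-wise composition but no inter-position dependence,
which is exactly what makes it the right null for subsite cooperativity.

## Analytics

Composition matrices are per-position residue frequencies, optionally
divided by a reference composition (the built-in natural table is the
Swiss-Prot average; background references must be strictly positive).
Position-wise KL divergence is KL(P‖Q) in nats with an additive pseudocount
α = 1 on counts (direction and α are configurable; reported values shift
under these choices). K-mer censuses count overlapping, position-independent
k-mers; the CDF accumulates frequency mass over unique k-mers sorted by
descending count; the overlap breakdown partitions the union of two k-mer
sets. Biophysical properties: aliphatic index
100·(f_A + 2.9 f_V + 3.9 (f_I + f_L)), mean Kyte–Doolittle hydrophobicity,
mean Boman scale, Henderson–Hasselbalch net charge with an EMBOSS-style pKa
set, and pI by bisection of the charge curve. Activity clustering is
average-linkage agglomerative clustering of protease columns under
1 − Pearson distance; the flat-group cutoff is an input, not a discovered
constant.

## Synthetic panel simulator

Ground truth per protease m: raw(s, m) = Σᵢ W_m[i, sᵢ] + Σ bonuses for
cooperativity k-mers present at their positions. Defaults: position weights
i.i.d. Normal(0, 0.5²); 3-mer cooperativity motifs (the granularity at which
contiguous-residue motifs matter for MMP cleavage), two shared motifs per
protease family with bonuses ~ Normal(1.5, 0.25²), and one private motif
(bonus 2.5) carried by a single designated protease — so a selective design
target provably exists. Libraries mix uniform-random 10-mers with
motif-implanted ones (implant probability 0.3, motif drawn uniformly from
the panel pool); Z standardizes raw + Normal(0, noise_sd²) per protease over
the library (noise_sd default 0.5, i.e. roughly 30% of the standardized
scale — a continuous normalized readout with visible but not overwhelming
noise). Zero-variance columns map to all-zero Z with a logged warning.

What the simulator does *not* emulate: sequencing-count noise, PCR bias,
enzyme kinetics, heteroscedastic per-substrate assay noise, or the
real screen's normalization pipeline (per-protease standardization here is
a stand-in). Consequently, passing benchmarks show that the architecture,
training loop, steering mechanism and score calculus work as specified on
data with the screen's coarse statistical structure — they are not evidence
about any particular real protease family.

## Benchmark problem sizes and numerical choices

The built-in benchmarks (also used by `scripts/acceptance.py`) run on one
CPU in minutes:

- Predictor recovery: M = 4 proteases, n = 4000 peptides, noise_sd = 0.5,
  K = 5 transformer members, 40 epochs, warmup 500; held-out evaluation on
  8000 independently simulated peptides scored on the training library's
  standardization scale. Reported: per-protease Pearson r, aggregate MAE
  relative to the irreducible-noise floor E|Z − Z_true|, and the pooled
  Spearman correlation between σ and |Ẑ − Z_true|. The calibration check
  uses the simulator's noiseless truth deliberately: the i.i.d. readout
  noise is uncorrelated with σ by construction and only dilutes the
  statistic; the underlying effect is real but weak (ρ ≈ 0.02–0.03 at this
  scale), which is why the evaluation set is large.
- Steering: M = 6, n = 3000, 20 generator epochs, warmup 300. 800
  unconditional (T = 1) vs 800 conditional (T = 1.2) generations seeded
  with the library's top-50 selective profiles; medians of true selectivity
  for the private-motif protease.
- Nomination: a K = 3, 25-epoch ensemble on the same library; 20 seeded
  repetitions of pool-generate → predict → rank → 5-mer filter → top 24,
  against equal-size site-independent baselines, scored by mean true Z for
  the target.

Numerical details: float64 throughout; Adam (β = 0.9/0.999, ε = 1e-8);
attention masks use additive −1e9 on PAD keys and causal positions;
sampling uses inverse-CDF draws from the temperature-scaled softmax (a
temperature → 0 recovers greedy decoding); library CSVs are written with
%.17g and read with round-trip float parsing so write→read is exact.

## Known limitations

- Parameter counts of the printed architectures are approximate (exact
  attention/feed-forward internals reproducing the published 56k/44k/328k
  counts are not recoverable); counts are logged, not asserted.
- The 80/20 split's random membership is not reproducible against the
  published split (seed unstated there); only its size is.
- Conditional training tags use the library's true Z rows; predicted
  profiles are used for seeding generation, as in the reference workflow.
- The uncertainty signal of a 5-member ensemble on homoscedastic synthetic
  data is weak; σ should be treated as a coarse ranking aid, not a
  calibrated error bar.
- Thresholds/quadrant analyses of a real fluorogenic screen require that
  screen's kinetics; the package ships the calculus and synthetic
  demonstrations only.
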