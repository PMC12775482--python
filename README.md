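# cleavekit

Design of protease substrates with learned sequence models.

Proteases recognize short peptide substrates through position-specific
subsite preferences and cooperative interactions between adjacent residues.
Finding substrates that a target protease — say, the collagenase MMP13 —
cleaves *efficiently* (high absolute cleavage) and *selectively* (preferring
it over its relatives) is a combinatorial search over ~20¹⁰ ten-mers, and
high-throughput screens that profile it (mRNA display against an 18-MMP
panel) are costly and rare. `cleavekit` implements an end-to-end in silico
design pipeline for this problem, aimed at protease biologists and protein
engineers:

- **Predictor** — multi-output regression from a peptide sequence *s* to
  per-protease cleavage Z-scores Ẑ_{s,m}, with two backbones (a 2-layer
  encoder-only transformer with CLS pooling, and a 2-layer bidirectional
  LSTM). An ensemble of K = 5 members, trained over independent 80/20
  train/validation resplits, gives each prediction an uncertainty
  σ_{s,m} = std of the member predictions.
- **Generator** — a decoder-only autoregressive transformer over residues,
  p(x) = ∏ᵢ p(xᵢ | x₁…xᵢ₋₁), trained 50% unconditionally and 50%
  conditioned on the sequence's own panel Z-profile (rounded to tenths),
  injected in place of the START token. At inference a conditioning tag
  steers generation toward a desired cleavage profile; sampling uses a
  temperature and a sign-aware repeat penalty on the previous token.
- **Score calculus** — selectivity S_{s,m} = Ẑ_{s,m} − mean_{i≠m} Ẑ_{s,i};
  in vitro efficiencies in [0, 1] from fluorogenic screen kinetics;
  per-protease cleavage thresholds T_m calibrated on screen labels
  (maximum Youden J along the ROC, with mean-imputation for unscreened
  proteases); corrected efficiency Ê = (Ẑ−T_m)/max(Ẑ−T_m) for Ẑ > T_m else
  0; corrected selectivity on Ê; and efficiency/selectivity quadrant
  assignment (cuts E > 0.4, S > 2.4).
- **Design** — uncertainty-aware ranking (Ẑ − σ), greedy 5-mer diversity
  filtering, site-independent baselines, end-to-end nomination.
- **Analytics** — position-composition (IceLogo-style) matrices with
  natural/background normalization, position-wise KL divergence, k-mer
  censuses/CDFs/overlap breakdowns, peptide biophysical properties, and
  hierarchical clustering of protease activity profiles.
- **Simulator** — a synthetic protease panel (position-weight matrices +
  subsite-cooperativity bonuses + Gaussian readout noise, standardized per
  protease) with protease families and one private-motif protease, so the
  whole pipeline is testable end to end with known ground truth.

The neural models run on a small self-contained NumPy autodiff engine
(`cleavekit.nn`); no GPU or deep-learning framework is required.

## Worked example

Simulate a 6-protease screen, train the generator, and steer it toward the
panel's selectivity-bearing protease:

```python
import numpy as np
import cleavekit as ck
from cleavekit import benchmarks as bm

ctx = bm.train_steering_context(seed=0)       # panel + library + generator
out = bm.conditional_steering(ctx, seed=0)
print(round(out["median_selectivity_unconditional"], 3),
      round(out["median_selectivity_conditional"], 3))
print({k: round(v, 3) for k, v in out["pathway_losses"].items()})
```

prints

```
0.091 0.862
{'unconditional': 2.56, 'conditional': 2.397}
```

i.e. conditioning the generator on high-selectivity profiles raises the
median true selectivity of its designs for the private-motif protease from
0.09 to 0.86 (Z-score units against the simulator's noiseless ground
truth), and the conditional pathway achieves lower held-out cross-entropy
than the unconditional one — the tag is informative.

The same workflows are exposed as a CLI:

```bash
cleavekit simulate --n 2000 --panel-size 6 --seed 7 --out runs/sim
cleavekit train-predictor --library runs/sim/library.csv --out runs/pred
cleavekit train-generator --library runs/sim/library.csv --out runs/gen
cleavekit generate --model runs/gen/generator.npz --n 1000 --seed 1 \
    --train-library runs/sim/library.csv --out runs/gens
cleavekit design --generations runs/gens/generations.fasta \
    --model runs/pred/predictor.npz --target PROT1 --n 24 --out nominees.csv
```

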