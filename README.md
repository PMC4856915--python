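# polysorb

Surrogate modelling of dynamic water uptake across polymer libraries from
small training sets.

## The problem

Water uptake — the mass of absorbed water as a percentage of a polymer
film's dry mass, `WU% = 100 · m_water / m_sample` — controls how a
degradable implant swells, softens, releases drug and erodes. Measuring
it is slow: films incubate for up to 42 days per polymer, so a
combinatorial library (e.g. the 112 L-tyrosine-derived polyarylates
obtained by pairing 14 diphenols with 8 diacids) cannot be characterized
exhaustively. `polysorb` builds a cheap empirical surrogate from a small
measured subset (typically 18 polymers) plus molecular descriptors
available for the whole library, and ranks the unmeasured polymers by
predicted equilibrium water uptake `WU_eq` with uncertainty bands.

The modelling recipe, aimed at the n ≈ 18 regime:

1. **Consolidation** — each WU(t) time series on the standard incubation
   grid (6 h, 12 h, 1–42 d) is reduced to `WU_eq ± SD` by averaging a
   late plateau window.
2. **Target discretization** — a K = 3 Gaussian mixture fitted by EM
   (best of many restarts, including contiguous-partition
   initializations) defines low/medium/high classes.
3. **Descriptor selection** — correlation-based feature selection scored
   by Hall's merit, `merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)`, searched
   with a bitstring genetic algorithm; a gain-ratio decision tree grown
   against the mixture classes ranks the subset; ordinary least squares
   on the standardized subset contributes one more descriptor (largest
   |coefficient|).
4. **Surrogate** — a multilayer perceptron (default one hidden layer of
   two sigmoid nodes, linear output) trained by online backpropagation
   with momentum (lr 0.3, momentum 0.2, 1000 epochs) on unit-interval
   scaled inputs; 100 random seeds are trained and the lowest training
   RMSE network kept.
5. **Validation** — every way of holding out 10 % of the polymers
   (C(18,2) = 153 leave-two-out splits) is evaluated; headline metrics
   are R² (squared Pearson), the fraction of predictions within each
   polymer's experimental SD, and low/medium/high class accuracy.
6. **Library prediction** — every split's model scores the unmeasured
   polymers; mean ± SD across splits is reported with a
   low/medium/high/very-high band and sorted from highest to lowest.

A synthetic-library generator with a planted sparse nonlinear
structure–property signal provides ground truth for end-to-end recovery
tests; a packaged reference table ships the measured `WU_eq ± SD` of 18
tyrosine-derived polyarylates (2.3 % to 136.5 %).

## Worked example

```python
import numpy as np
from polysorb import GeneratorConfig, ModelingDataset, WaterUptakeModel, generate_library

# 56-polymer synthetic library; the first 18 polymers are "measured"
table, series, eqs, truth = generate_library(GeneratorConfig(n_polymers=56, seed=11))
train = table.rows(list(table.polymer_ids[:18]))
dataset = ModelingDataset.from_equilibrium(train, eqs[:18])

model = WaterUptakeModel(dataset, seed=7)
results = model.fit()
print(results.summary())

library = table.rows(list(table.polymer_ids[18:]))
predictions = results.predict_library(library)
print("top of the ranked library (mean +/- SD, band):")
for p in predictions[:5]:
    print(f"  {p.polymer_id}  {p.mean_pred:6.1f} +/- {p.sd_pred:4.1f}  {p.band}")
```

prints

```
Water-uptake surrogate model
============================================================
target:                 equilibrium
n units:                18
descriptors screened:   300
selected descriptors:   inf_02, red_03_of_00, red_02_of_02
  via tree ranking:     inf_02
  via regression:       red_03_of_00
CFS merit of subset:    0.9732
mixture classes (mean WU): low=56.7%, medium=87.4%, high=106.3%
best-of-100 seeds train RMSE: 9.969 %
------------------------------------------------------------
cross-validation:       153 splits (exhaustive)
R^2 training (mean over splits):   0.861
R^2 cross-validation (pooled):     0.481
within experimental SD (training): 27%
within experimental SD (test):     17%
class accuracy (test, low/med/high): 72%

top of the ranked library (mean +/- SD, band):
  polymer_025   129.8 +/- 13.4  very_high
  polymer_052   113.0 +/- 18.2  very_high
  polymer_036   106.6 +/- 10.4  high
  polymer_027   105.2 +/-  6.2  high
  polymer_018   103.4 +/-  4.6  high
```

Here the cascade picked one planted informative descriptor plus two
redundant copies of informative descriptors (names starting `inf_` /
`red_`); cross-validated R² of 0.48 and 17 % of held-out polymers
predicted within their experimental SD are typical for 18 training
polymers at the default noise level, and the ranked library recovers the
truly high-uptake polymers at the top.

The same workflow is scriptable from the shell:

```sh
polysorb --config run.yaml --seed 7 --outdir run run-all
polysorb --config run.yaml --outdir run compare-targets
```

`compare-targets` contrasts the consolidated-`WU_eq` model with the
model trained on every (time, WU) point, cross-validated both row-wise
(the permissive protocol — rows of one polymer can land on both sides of
a split) and grouped by polymer (honest).

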