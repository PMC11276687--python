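# grasshab

Presence-only maximum-entropy (MaxEnt) habitat-suitability modelling
for grassland pest species — built for analyses like mapping where the
steppe grasshopper *Oedaleus decorus asiaticus* can breed, from
environmental raster layers and field presence records.

Surveys of grassland pests record *where an outbreak-level density was
observed*, never where the species is absent. MaxEnt handles exactly
this setting: it contrasts the environment at presence locations with a
background sample of the landscape and fits the most spread-out (maximum
entropy) probability distribution consistent with the presence data.
`grasshab` implements the full analysis pipeline around a from-scratch,
certificate-checked MaxEnt core:

- **Synthetic landscapes** — smooth correlated covariate rasters,
  categorical vegetation/soil layers, a known true response, and
  presences marked where simulated density exceeds an outbreak
  threshold (15 insects/m²), so the whole pipeline is testable without
  restricted survey data.
- **Preprocessing** — fractional vegetation cover from NDVI (dimidiate
  pixel model), maximum-value compositing, ordinary kriging of station
  data, and raster alignment (bilinear / nearest-neighbour).
- **Screening** — Pearson collinearity pruning (drop one of each pair
  with |r| > 0.8).
- **MaxEnt core** — L/Q/P/T/H feature expansion, L1-regularized Gibbs
  fitting with a numerical KKT certificate, logistic suitability
  output, response curves, permutation importance, percent
  contribution, and jackknife gains.
- **Calibration** — a regularization-multiplier × feature-class
  candidate grid scored by partial-ROC significance, omission rate and
  AICc; selection by significance → omission ≤ 8% → minimum AICc.
- **Mapping** — replicated fits, mean suitability rasters, four
  suitability classes (breaks 0.25/0.5/0.75) and an area/percentage
  table.

## The model

With features `f_i` (linear, quadratic, product, threshold and hinge
transforms of covariates, plus categorical indicators) and a background
sample of the landscape, the fitted distribution over background cells
is the Gibbs form

    P_w(x) = exp(Σ_i w_i f_i(x)) / Z_w

with weights minimising the penalized negative mean presence
log-likelihood `log Z_w − mean_pres(Σ w_i f_i) + Σ_j RM·β_j|w_j|`.
Every converged fit satisfies, and the tests verify,
`|E_model f_j − mean_pres f_j| ≤ RM·β_j` with equality on active
features. Suitability is the entropy-calibrated logistic transform
`r·e^H/(1 + r·e^H)` of the raw score `r`. See `docs/methods.md` for the
full account.

## Worked example

Run the pipeline end to end on a synthetic landscape (the `simulate`
block is replaced by a `data` block pointing at GeoTIFFs and an
occurrence CSV for real data):

```yaml
# example.yml
seed: 7
simulate: {nrows: 60, ncols: 60, n_occurrences: 150}
background: 3000
calibration:
  rm_start: 0.5
  rm_stop: 2.0
  rm_step: 0.5
  fc_list: [L, LQ, LQH]
  proc_iters: 300
replicates: {n: 5}
n_knots: 10
```

```sh
grasshab run --config example.yml --out demo
```

prints

```
suitability shares: unsuitable=52.54%, low=26.23%, moderate=21.13%, high=0.10%
```

and `demo/selection_report.txt` records the calibration outcome:

```
candidate models: 12
fitted: 12
statistically significant: 12
omission <= cut: 9
AICc-eligible: 9
selected: RM=2 FC=LQH (AICc=2251.9791, omission=0.0526, p=0, k=14)
```

Twelve candidates (RM 0.5–2 × three feature combinations) were fitted
on a fixed 75/25 presence split; all were significantly better than
random under the partial-ROC test, nine kept test omission under the 8%
cut, and the minimum-AICc model (RM 2, linear+quadratic+hinge features,
14 active weights) won. The selected model was then re-fitted on 5
replicate splits and its mean logistic surface classified: about half
the landscape is unsuitable and 0.1% highly suitable.

`demo/importance.csv` shows which covariates the model relies on:

```
variable,permutation_importance,percent_contribution
fvc,66.07845946,72.42769559
soil,31.34475825,25.31048513
dem,1.336804612,1.162127903
```

Vegetation cover and soil type dominate both importance readouts — and
they are exactly the two variables that drive the synthetic truth, so
the pipeline recovered the generative structure. Response-curve tables
(`demo/response_*.csv`), the mean suitability and class GeoTIFFs, the
candidate table and a seeded run manifest land in the same directory.

The same stages are available as library calls (`grasshab.fit`,
`grasshab.run_calibration`, `grasshab.replicate_runs`, …) and as CLI
subcommands (`simulate`, `preprocess`, `screen`, `calibrate`, `fit`,
`predict`, `run`).

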