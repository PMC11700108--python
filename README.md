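# fruitmass

Non-destructive fruit weight estimation from image-derived dimensions.

The package implements a complete, testable pipeline for estimating the
fresh weight of single fruits (plums) from two dimensions — maximum length
L and maximum equatorial diameter D — measured in top-view images:

- **`fruitmass.synthetic`** — ground-truthed inputs: tabular (L, D, FW)
  cohorts drawn from truncated correlated bivariate normals with a
  configurable allometric weight-generating law, plus rendered single-fruit
  images (elliptical fruit, green/yellow/red hues, illumination gradient,
  sensor noise) and calibration-square images. Five bundled cohort recipes
  (`DEFAULT_COHORTS`) emulate the field datasets the method was developed on.
- **`fruitmass.segmentation`** — RGB → CIELAB (sRGB/D65), 2-cluster K-means
  on the (a\*, b\*) chroma channels only (so the result is robust to the
  fruit's hue and to smooth lighting changes), border-majority background
  selection, morphological opening (disk, r = 5 px), hole filling, largest
  component.
- **`fruitmass.morphometry`** — pixel→mm calibration from a 10×10 mm
  reference square; L and D as the mask extents along/perpendicular to the
  second-moment major axis.
- **`fruitmass.models`** — the weight estimators: five allometric forms
  FW = a + b·f(L, D) with f ∈ {L·D, L³, D³, L·D², L²·D} (exact closed-form
  least squares), multiple linear regression, ε-SVR with RBF / Pearson-VII
  (PUK) / degree-2 polynomial kernels and c ∈ {0.1, 1, 10} grid search,
  a one-hidden-layer tanh perceptron (2–h–1, h ∈ [1, 20]), and an M5-style
  model tree with linear leaves, pruning and smoothing. All models
  serialize to JSON.
- **`fruitmass.evaluation`** — RMSE, R², seeded 70/30 splits (half-up train
  rounding), 10-fold validation indices, best-model selection, descriptive
  statistics, Pearson correlation matrices, 1:1-line diagnostics, and
  cross-cohort transfer validation of frozen models.
- **`fruitmass.cli`** — a Typer CLI orchestrating everything from a single
  YAML config with one root seed.

## CLI

```bash
# generate cohort CSVs (and images, if images_per_cohort > 0)
fruitmass simulate --config config.yaml

# measure a directory of fruit images against a calibration image
fruitmass measure --images imgs/ --calibration cal.png --out dims.csv

# fit one model family on a cohort CSV
fruitmass fit --data plum-2019.csv --model svr --kernel PUK --c 1 --out model.json

# apply a frozen model to another cohort
fruitmass evaluate --data gavali-2021.csv --model model.json

# full study: fit all families, evaluate, pick a winner, transfer-validate
fruitmass study --config config.yaml
```

Minimal config:

```yaml
seed: 1
output_dir: out
development_cohort: plum-2019
cohorts:
  - preset: plum-2019
  - preset: gavali-2021
  - preset: ghandi-2021
  - preset: shahryari-2021
  - preset: jangali-2021
models:
  svr: {kernels: [RBF, PUK, POLY2], c_values: [0.1, 1, 10]}
  mlp: {h_values: [1, 2, 3, 4, 5]}
```

`fruitmass study` writes `fitted_forms.csv`, `ml_models.csv`, `svr_grid.csv`,
`transfer_validation.csv`, descriptive statistics, plots (1:1 scatter,
histograms, correlation heat map) and a manifest with the config hash.

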