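# File formats

All interchange formats are plain text (UTF-8, comma-separated, `.`
decimal). Floats are written with 17 significant digits so a write/read
round trip is bit-exact.

## Connectivity matrix (CSV)

N×N symmetric Pearson matrix with region ids as both header and index:

```
,roi0,roi1,roi2
roi0,1,0.52,-0.13
roi1,0.52,1,0.40
roi2,-0.13,0.40,1
```

Validation on read: square shape, no NaN, entries in [-1, 1], symmetry
to 1e-8 (smaller asymmetries are averaged away), unit diagonal.

## ROI time series (TSV/CSV)

T rows × N columns, header row = region ids; `.tsv`/`.txt` are
tab-separated, `.csv` comma-separated. At least 3 timepoints, no missing
values.

## Dataset manifest (CSV)

```
sample_id,path,label
sub-001,matrices/sub-001.csv,0
sub-002,matrices/sub-002.csv,1
```

Paths are resolved relative to the manifest's directory; labels are 0
(negative / control-like) or 1 (positive); sample ids must be unique.
If the paths end in `.tsv`/`.txt` the rows are treated as time series
and run through the Pearson construction pipeline.

## Synthetic dataset directory (`braingat simulate --out DIR`)

```
DIR/manifest.csv          sample_id,path,label
DIR/matrices/*.csv        headerless-index N×N weight tables (header 0..N-1)
DIR/ground_truth.json     selected_nodes, w0_mean, w0_values, spec
```

## Feature mask / saliency scores (CSV)

N×F matrix of scores, one header row of feature indices. Row = node,
column = feature.

## Reports (JSON)

Cross-validation reports:
`{"model", "folds": [{accuracy, sensitivity, specificity, f1, auc,
mcc}, ...], "mean": {...}, "std": {...}, "config_echo", "version",
"seed"}`. Perturbation reports: `{"reports": [{k, cpp, nlci,
metrics_after}, ...]}`.

## Run configuration (YAML)

Top-level keys `model`, `training`, `baseline`, `interpretation`
(unknown top-level keys are rejected), e.g.

```yaml
model: {heads: [4, 4], units: [16, 16]}
training: {max_epochs: 350, folds: 5, learning_rate: 0.0001}
interpretation: {steps: 200, l1_coef: 0.005}
```

## Checkpoints (JSON)

Flat named-tensor archive: model class name, node/feature counts and
the parameter arrays in `parameters()` order. Restore with a model built
with the same architecture options.
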