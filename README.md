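# ckdfusion

Graph + tabular late-fusion deep learning for chronic kidney disease (CKD)
prediction from routine clinical features.

The package builds a weighted k-nearest-neighbour patient-similarity graph
over a clinical feature table, trains a graph-convolutional branch and a
feed-forward tabular branch, and fuses their embeddings through
dimension-matching transforms and an elementwise-averaging head into a
single per-patient probability. It ships the full preprocessing chain
(median/mode imputation or complete-case filtering, IQR winsorization,
min-max / z-score normalization, from-scratch SMOTE oversampling), a
stratified train/val/test protocol, grid search, a four-model comparison
(fusion / GNN / tabular / logistic baseline), and a synthetic cohort
generator so everything is testable offline.

Models are implemented in pure numpy on a small reverse-mode autodiff core
(validated against finite differences in the test suite); the GNN is
transductive — one fixed graph over all patients with supervision
restricted to training-role nodes.

## CLI

Everything is driven by one YAML config:

```yaml
# config.yaml
input:
  synthetic: {n_per_class: 200, mode: clinical, missing_rate: 0.1}
  # or: uci_path: data/chronic_kidney_disease.arff
  # or: csv_path: mytable.csv        # header row, '?' = missing
preprocess:
  impute_strategy: median_mode       # or complete_case
  normalize: minmax
  smote: {enabled: true, target_total: 2000, k_neighbors: 5}
  split: {fractions: [0.7, 0.15, 0.15]}
graph: {k: 5, metric: euclidean, scheme: sym, use_weights: true}
train: {epochs: 200, learning_rate: 0.05, optimizer: adam}
master_seed: 1
output_dir: run_output
```

```bash
ckdfusion run --config config.yaml
ckdfusion report --metrics run_output/metrics.json
```

Re-running with the same config produces byte-identical metric artifacts;
per-stage seeds are derived deterministically from `master_seed`.

Individual stages are exposed as subcommands (`simulate`, `preprocess`,
`build-graph`, `train`, `gridsearch`, `compare`, `report`); see
`ckdfusion <cmd> --help`.

## Real data

The public UCI chronic-kidney-disease table (400 records, 24 features,
'?' for missing, 158 complete cases) is read in its original ARFF dialect
or as a CSV export. It is not redistributed here: download it from the UCI
Machine Learning Repository and place it at
`data/chronic_kidney_disease.arff` (or set `CKD_UCI_PATH`). The
UCI-dependent tests and acceptance targets activate automatically when the
file is present.

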