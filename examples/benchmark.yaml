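# Minimal end-to-end benchmark grid for `splitshift run`.
# Generates a synthetic library, builds label-shift-controlled splits for
# each splitter, computes 5-NN Tanimoto shift profiles, trains each model,
# and writes results.json / report.json / manifest.json to --out-dir.
seed: 11
simulate:
  n_molecules: 500
  n_scaffold_templates: 10
  active_fraction: 0.45
  label_noise: 0.1
splitters: [random, scaffold, kmeans]
models: [rf, xgb]
replicates: 2
ood_fraction: 0.2
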