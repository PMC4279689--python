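# synforest

Synthetic random forests over a terminal-nodesize grid.

A forest's `nodesize` (minimum cases per terminal node) acts as a smoothing
bandwidth, and its best value depends on the data — sometimes on the region
of the feature space. `synforest` sidesteps global tuning: it grows a
portfolio of forests across a nodesize grid, takes each machine's
**out-of-bag (OOB) predictions** as new *synthetic features* (one column per
machine in regression, the first J−1 class probabilities in multiclass), and
fits a secondary **hyperforest** on the original features plus the synthetic
columns. Node splits of the hyperforest can then choose locally among
smoothing bandwidths.

The package ships with the natural comparators and a benchmark harness:

- **RF** — a standard forest at the hyperforest's nodesize (default 5);
- **RFopt** — the single grid forest whose nodesize minimizes OOB error;
- **COBRA** — a regression collective over the same grid machines:
  zero-one proximity-of-predictions weights with a brute-force ε
  calibration over a 200-point grid (regression only);
- seeded generators for the classic simulated benchmarks (Friedman #1/2/3
  regression surfaces; twonorm / threenorm / ringnorm Gaussian two-class
  mixtures; optional appended noise features);
- evaluation: standardized MSE (100 = uninformed baseline), normalized
  Brier score ×100 (25 = uniform guessing for every class count), 10-fold
  CV and train/test replication protocols, exact Wilcoxon signed-rank and
  Iman–Davenport modified Friedman ranking statistics.

## Library quick start

```python
import synforest as sf

data = sf.generate(sf.GeneratorSpec(name="friedman1", n=250, seed=1))
model = sf.fit_srf(data, sf.SyntheticConfig(seed=7))
test = sf.generate(sf.GeneratorSpec(name="friedman1", n=5000, seed=2))
print(sf.standardized_mse(test.y, sf.predict_srf(model, test.X)))
print(model.rfopt_nodesize)  # the OOB-optimal grid value
```

Defaults follow the benchmark protocol: `ntree=500`,
`mtry = first integer > p/3` (recomputed on p+q for the hyperforest),
nodesize grid `(1..10, 20, 30, 50, 100)` pruned to values < n, hyperforest
nodesize 5. All stages are deterministic given the config seed.

Two nodesize enforcement modes are available
(`SyntheticConfig(nodesize_semantics=...)`): `"split"` (default) makes any
node with fewer than `2*nodesize` cases terminal, matching the effective
behaviour of the reference forest engine, while `"leaf"` enforces at least
`nodesize` unique in-bag cases per terminal node (the strict minimum-leaf
reading; noticeably smoother at equal nodesize).

## CLI

```bash
synforest simulate --name friedman1 --n 250 --seed 1 --out data.csv
synforest fit --data data.csv --seed 7 --out model.joblib
synforest predict --model model.joblib --data new.csv --response y --out preds.csv
synforest benchmark --config run.yaml
synforest rank --results run/results.csv --out ranks.csv
```

A benchmark config file (YAML or JSON) mirrors the `RunConfig` fields;
`seed` is mandatory and exactly one of `generator` / `input_path` must be
given:

```yaml
task: regression
methods: [RF, RFopt, SRF, COBRA]
seed: 1
generator: {name: friedman1, n: 250}
reps: 100
n_test: 5000
output_dir: runs/friedman1
```

Simulated inputs are scored on independent size-`n_test` test sets per
replication; CSV inputs are scored by seeded 10-fold cross-validation.
`results.csv` holds per-replication rows, `summary.csv` the per-method
means, and `run_log.json` the resolved settings and seeds; reruns of the
same config are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `synforest.forest_core` | `Dataset`, forest fitting with explicit inbag matrices, full and OOB prediction |
| `synforest.synthetic_forest` | nodesize-grid machines, synthetic features, hyperforest, RFopt selection |
| `synforest.cobra` | zero-one-weight collective prediction and ε calibration |
| `synforest.datagen` | seeded benchmark generators |
| `synforest.metrics` | standardized MSE, normalized Brier |
| `synforest.evaluation` | CV/replication harness, Wilcoxon + Iman–Davenport statistics |
| `synforest.cli` | CSV/config I/O and the `synforest` command |
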