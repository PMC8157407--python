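# interpbench

Benchmark construction and evaluation toolkit for **interpretability of
QSAR models**. It generates synthetic molecular datasets where every atom
has a known expected contribution ("ground truth"), trains conventional
fingerprint models, computes atom/fragment contributions by virtual
removal (dummy-atom masking), and quantifies interpretation quality with
per-molecule ranking and error metrics.

## What is inside

| Module | Role |
| --- | --- |
| `interpbench.chem_io` | molecule/dataset I/O, standardization, deterministic fixture pool generation |
| `interpbench.ground_truth` | the six labeling rules: nitrogen count, N−O, N+O (correlated patterns), amide regression/classification, two-point 3D pharmacophore (HBD–HBA 9–10 Å) |
| `interpbench.dataset_builder` | normal-shaped regression sampling, balanced classification sampling, 70/30 splits, correlation bias audit |
| `interpbench.descriptors_models` | AP / MG2 / RDK / TT fingerprints (counted unfolded + binary 2048-bit), RF / PLS / GBM / SVM harness with 5-fold CV grid search, 1-NN modelability baseline |
| `interpbench.interpretation` | dummy-atom masking, atom & fragment contributions, acyclic-bond fragment enumeration (≤ 3 bonds, ≤ 7 atoms, ≤ 40 % of molecule) |
| `interpbench.metrics` | Q²/RMSE, sensitivity/specificity/balanced accuracy, per-molecule AUC⁺/AUC⁻, top-n/bottom-n, contribution RMSE, top-k %, fragment top-2, pattern-count breakdown |
| `interpbench.cli_bench` | `interpbench` CLI and full-benchmark orchestration with manifests |

Contributions are model-agnostic: any
`PredictorHandle` or any callable `f(record, masked_atom_set) -> float`
(e.g. a graph-model row-removal predictor) plugs into the same
interpretation contract.

## CLI

```bash
# build one labeled dataset (CSV + ground-truth JSONL + bias audit)
interpbench generate --task N --size 600 --pool-size 2000 --seed 1 --out datasets/

# train one model on its training split
interpbench train --dataset datasets/N.csv --task-kind regression \
    --fingerprint MG2 --counted --algorithm GBM --model-out model.joblib

# masking-based contributions for the training split
interpbench interpret --model model.joblib --dataset datasets/N.csv \
    --level atom --out contribs.jsonl

# interpretation-quality report
interpbench score --contributions contribs.jsonl \
    --truth datasets/N_truth.jsonl --out report.json

# or run the whole grid from a YAML config
interpbench run --config config.yaml
```

Example `config.yaml`:

```yaml
tasks: [N, amide_class]
fingerprints:
  - {family: MG2, counted: true}
  - {family: AP, counted: true}
algorithms: [GBM, RF]
seed: 1
pool_size: 2000
dataset_size: 600
out_dir: benchmark_out
```

Interpretation is evaluated on the **training split** by default (smaller
prediction error), matching the benchmark protocol.

## Notes

- Atom indices are frozen at parse time from the canonical SMILES output
  order; all truths and contributions refer to these indices.
- Counted fingerprints stay unfolded so features introduced by dummy
  atoms are exactly out-of-vocabulary and therefore ignored by models;
  binary fingerprints are folded to 2048 bits (hash collisions with dummy
  features are an accepted artifact).
- The H-bond donor/acceptor SMARTS table ships at
  `src/interpbench/data/hbond_smarts.txt`.
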