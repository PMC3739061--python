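# modreorg

Modular-reorganization analysis of resting-state brain connectivity
networks, as a tested, reusable Python pipeline:

- **Per-subject networks** — zero-lag Pearson correlation (`CC`) between
  region-averaged time courses, with the `d = 1 − CC` distance view.
- **Group networks** — entrywise mean divided by entrywise (population)
  standard deviation across subjects, positive-masked.
- **Modularity** — weighted modularity `Q`, Newman-style leading-eigenvector
  module detection with Kernighan–Lin refinement, degree-preserving
  (double-edge-swap) null networks, and Q-vs-edge-count group comparisons
  with Bonferroni correction.
- **Reorganization** — source→target module flow maps between two group
  partitions and detection of homotopic (left/right mirror) pairs whose
  members land in different modules.
- **Biomarkers** — index A (mean homotopic connectivity over a designated
  pair set), index B (mean unilateral connectivity within the set),
  module-averaged gray-matter concentration (GMC), GMC residualization,
  Welch group statistics, and in-sample ROC/AUC for single or
  logistic-combined features.
- **Synthetic cohorts** — multivariate-normal subjects with planted modular
  covariance, group-specific interhemispheric coupling on a designated pair
  set, and group-shifted GMC, so every stage is testable end-to-end with
  known ground truth.

A 116-region atlas fixture (54 homotopic pairs, 8 midline regions,
conventional AAL ordering) ships with the package, including the
`insula_module_pairs` subset of 8 bilateral pairs; any atlas TSV with the
same columns is accepted.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end guarantees (brute-force
modularity oracle, null separation, planted-partition and planted-split
recovery, biomarker power/size, closed-form AUC, byte-level determinism);
the rest are per-module unit and property tests. The full suite takes a
few minutes (dominated by the null-network simulations).

## CLI

```sh
modreorg simulate       --out sim/ --n-per-group 30 -t 175 --seed 1
modreorg connectivity   --in sim/ --out cc/
modreorg group-network  --in cc/  --atlas sim/atlas.tsv --out gn/
modreorg modules        --network gn/group_CN.tsv --atlas sim/atlas.tsv --out partition_CN.tsv
modreorg q-curve        --in cc/ --atlas sim/atlas.tsv --grid 200:2000:200 --nulls 100 --seed 1 --out qcurve.json
modreorg reorganize     --source partition_CN.tsv --target partition_AD.tsv --atlas sim/atlas.tsv --out reorg.json
modreorg indices        --in cc/ --atlas sim/atlas.tsv --gmc sim/gmc.tsv --out biomarkers.tsv
modreorg classify       --table biomarkers.tsv --features index_A,gmc_module_mean --out roc.json
modreorg run-all        --seed 1 --out results/
```

All matrices and tables are TSV with 1-based region-id headers; summaries
are JSON. `run-all` chains every stage on a synthetic cohort and writes a
manifest recording config, seed and versions; identical config + seed
reproduce byte-identical outputs.

Note: ROC/AUC values are in-sample (resubstitution) estimates, fitted and
evaluated on the same subjects — optimistic for unseen data by design.

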