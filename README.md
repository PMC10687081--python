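# trilokit

Landmark-based geometric morphometrics for trilobite cephala and
pygidia: shape-file IO, a fixed landmark standard with validation,
arc-length semilandmark resampling, generalised Procrustes
superimposition, covariance-PCA morphospaces, disparity metrics
through time, and measurement-error statistics — plus a synthetic-data
generator so the whole pipeline is testable without any downloads.

## What it does

- **`trilokit.shapeio`** — read/write the two shape-file dialects
  (classic `*.tps` keyword records and the tag-block `*.txt` format of
  R digitisers, one file per specimen per structure, named
  `<ID>_C.*` / `<ID>_P.*`), the specimen metadata YAML, and the
  references CSV. Coordinates are stored in physical units; unscaled
  files are flagged, never dropped.
- **`trilokit.template`** — the landmark standard: 16 landmarks and 4
  curves on the cephalon, 7 and 3 on the pygidium, with curve
  start/end landmark bindings and optionally-absent eye landmarks
  (LM8/LM9/LM14) for blind taxa. `validate()` is the homogeneity
  check; `mirror()` reflects left-sided specimens.
- **`trilokit.resample`** — `resample_curve()` places k equally spaced
  points along each curve's piecewise-linear interpolant;
  `fix_shapes()` validates, resamples and stacks specimens into a
  `(points × 2 × specimens)` array, dropping non-conforming specimens
  (or, with `policy="drop_trait"`, the offending traits) and
  deduplicating curve endpoints against their bound landmarks — with
  curve counts `12,20,20,20` a cephalon yields 80 points.
- **`trilokit.procrustes`** — `opa()` (two-shape, SVD, proper
  rotations only), `gpa()` (iterative alignment to a renormalised
  consensus), tangent-space `pairwise_distances()`.
- **`trilokit.morphospace`** — covariance PCA with deterministic
  eigenvector signs, virtual-shape reconstruction at arbitrary score
  vectors, per-interval occupancy tables, scatter plots.
- **`trilokit.disparity`** — SoV / SoR / NND, stage binning from
  min/max stage ages (a Devonian stage table ships built in),
  bootstrapped disparity through time, and range-through richness
  from occurrence tables.
- **`trilokit.error_analysis`** — per-group pairwise distances,
  Kruskal-Wallis with tie correction, a PERMDISP-style multivariate
  dispersion test (parametric and permutation p), Tukey HSD on the
  dispersions, and `error_report()` tying it together, optionally
  with a landmark-only vs full-configuration contrast.
- **`trilokit.synthetic`** — template-conforming fake datasets with
  known genus structure, digitising noise, nuisance similarity
  transforms and defect injection; plus the replicate-digitisation
  error experiment (within-observer / among-observer / among-genus
  groups, optional misplaced-LM15 variant).

## CLI

The `trilokit` entry point wires the workflow; every stochastic
subcommand requires an explicit `--seed`, and every run writes a
`manifest.json` sufficient to reproduce it.

```sh
trilokit simulate --n-genera 10 --n-per-genus 3 --seed 42 --out data/
trilokit validate --input data/ --no-require-scale
trilokit fix      --input data/ --structure cephalon --curves 12,20,20,20 --out fixed/
trilokit gpa      --input fixed/fixed.tps --out gpa/
trilokit pca      --input gpa/aligned.tps --out pca/
trilokit disparity --scores pca/scores.csv --bins bins.csv --seed 3 --out disp/
trilokit richness  --occurrences occ.csv --out rich/
trilokit error     --input shapes/ --groups groups.csv --reference among_genus \
                   --n-perm 9999 --seed 17 --out err/
```

Tabular outputs are CSV; shapes are written as tps. Exit codes: 0 on
success, 1 when validation finds non-conforming specimens, 2 on usage
errors.

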