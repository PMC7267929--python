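# cobedis

Common-component extraction across repeated scans and maximal-dissimilarity
subgrouping, exercised entirely on synthetic data with planted structure.

Given several runs of a parcellated time series per subject (regions x
timepoints), the package:

1. **decomposes** each subject's runs into a *common* spatial component
   shared by all runs plus run-specific subspaces (each run is reduced to an
   orthonormal basis of its leading column space; the common directions are
   the leading eigenvectors of the summed subspace projectors);
2. **correlates** the per-subject common components (Pearson, subject x
   subject);
3. **selects** a maximal-dissimilarity (MCD) subject group by randomized
   maximal-set growth under an |r| < 0.75 threshold with 1,000 restarts,
   keeping the restart with the smallest within-set maximum |r|; the
   complement forms the similarity (CS) group;
4. **summarizes** component weights over 17 cortical network labels + 19
   subcortical ROIs and contrasts MCD vs CS per label (Welch t, Bonferroni);
5. **compares** the groups on a 69-measure behavior battery (Welch t,
   Bonferroni), tests sex composition (Pearson chi-square), and re-tests
   against a random sex-matched (RSSM) subset of CS;
6. **simulates** complete datasets with a planted per-subject map, a
   planted dissimilar subgroup with reduced DMN-A-analog weights, planted
   behavioral effects on five substance-use/antisocial-like measures, and
   sex imbalance — so every stage is testable without any data download.

## CLI

```sh
# generate a synthetic dataset
cobedis simulate --out data/ --seed 1

# full pipeline on it
cobedis run-all --data-dir data/ --out results/run1 --seed 1

# or stage by stage
cobedis decompose --manifest data/manifest.csv --out components.tsv
cobedis correlate --components components.tsv --out correlation.tsv
cobedis select    --correlation correlation.tsv --out groups.csv --seed 1
cobedis sweep     --correlation correlation.tsv --thresholds 0.6,0.7,0.75,0.8

# template region -> network lookup (100 or 419 regions)
cobedis make-lookup --regions 419 --out lookup419.tsv
```

`run-all` also accepts a YAML config (`--config pipeline.yaml`) with
sections `paths`, `cobe` (`n_components`, `rank_energy` / `rank_fixed` /
`rank_noise_floor`, `demean_rows`), `selection` (`threshold`, `n_restarts`,
`seed`), `comparison` (`alpha`, `network_label`) and `rssm`. All stage
outputs are plain TSV/CSV/JSON files in the run directory, and a
`report.json` records per-stage status, timing and sha256 digests. Fixed
config + seed gives byte-identical outputs.

## Input formats

- **manifest.csv** — `subject_id,run_index,path`; each path points to a
  headerless TSV matrix, regions x timepoints, paths relative to the
  manifest.
- **lookup.tsv** — `region_index,region_name,label,hemisphere`, covering
  1..P exactly once.
- **behaviors.csv** — `subject_id,sex,<measure columns>` (complete cases
  only) with a companion **categories.tsv** (`measure,category`).

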