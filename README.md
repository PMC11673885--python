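# lesioncount

Quantification of retinal microvascular lesions from binary segmentation
masks, and severity analysis across the ICDR scale.

The pipeline:

1. **count** — per-lesion-class binary masks (PNG/TIFF) are decomposed into
   lesion instances by connected-components labeling plus a per-component
   marker-controlled watershed that splits touching lesions (markers =
   Euclidean-distance-transform maxima). Counts microaneurysms (MA),
   hemorrhages (Hma), hard exudates (HE); red lesions (RL) are derived as
   MA + Hma; HE area is measured in pixels and as an image fraction.
2. **filter** — records whose MA or Hma count falls outside
   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` of their dataset × grade stratum are
   excluded, with a fully auditable report.
3. **stats** — per-stratum means with 95% CIs, two-sided Wilcoxon rank-sum
   (Mann–Whitney) comparisons between severity grades with `***`/`**`/`*`/NS
   labels, and sample-size-weighted cross-dataset pooling.
4. **classify** — a single-hidden-layer neural network (7 logistic units,
   L2 penalty 0.001, stratified 80/20 split, train-only feature scaling)
   predicts the ICDR grade from lesion counts; reports a 4×4 confusion
   matrix, accuracy and per-class sensitivity.

A **synthetic-data** module generates (a) masks with planted, optionally
overlapping disk lesions plus matching XML centroid ground truth, and (b)
multi-dataset count tables drawn from zero-inflated negative-binomial
severity profiles calibrated to published per-grade means — so the whole
pipeline is testable without clinical data.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: calibration
recovery of published per-stratum means, exact counting and statistics
oracles (flood-fill components, full-enumeration rank-sum p-values,
hand-computed quartiles, type-I error calibration), severity-trend
recovery, and classifier behaviour.

## CLI

```bash
# synthetic cohort with masks + manifest (or --counts-only for a table)
lesioncount simulate --out data/ --seed 1

# individual stages
lesioncount count    --manifest data/manifest.csv --out counts.csv
lesioncount filter   --counts counts.csv --out run/
lesioncount stats    --counts run/counts_filtered.csv --out run/
lesioncount classify --counts run/counts_filtered.csv --out run/ --seed 1

# everything at once (figures, reports, run manifest)
lesioncount run-all --counts counts.csv --out run/ --seed 1
```

Useful flags: `--no-filter`, `--pairs {adjacent,all}`,
`--features MA,Hma,HE`, `--quantile-type {linear,lower,higher}`,
`--config config.yaml` (see `PipelineConfig`).

## Layout

```
src/lesioncount/
  types.py      shared domain types (grades, lesion classes, masks, manifests)
  io.py         mask/XML/manifest/count-table readers and writers
  counting.py   connected components + watershed instance counting, HE area
  filtering.py  1.5*IQR outlier exclusion with audit report
  stats.py      summaries, rank tests, weighted cross-dataset pooling
  classify.py   count-based severity classifier
  synth.py      planted-lesion masks and calibrated cohort generator
  pipeline.py   stage orchestration
  cli.py        click command line
  plots.py      severity and confusion-matrix figures
```
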