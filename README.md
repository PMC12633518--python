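# netfp

Single-subject inter-regional pharmacokinetic similarity networks for
dynamic brain PET.

Each scan's regional time-activity curves (TACs) are reduced to a
4-element feature vector per region — SUV at 1.25, 13.5 and 50 minutes
post-injection, plus the blood-to-brain influx rate K1 from a single
irreversible one-tissue compartment model driven by an image-derived input
function. Features are robust z-scored within tracer group (median / raw
MAD), and every region pair gets a similarity

```
S_ij = 1 / (1 + d_ij)
```

with `d_ij` the Euclidean distance between the standardized feature
vectors. The upper triangle of the 87×87 matrix (full bilateral
Desikan–Killiany cortex, bilateral subcortical structures, bilateral
cerebellar cortex, brainstem) is the scan's edge vector, on which the
downstream analyses operate:

- **harmonization** — per-edge OLS confound models (batch, sex, genotype,
  age, dose/weight) fitted on healthy controls only, residualization that
  preserves effects outside the design, and Cohen's-d summaries of
  standardized beta distributions;
- **reliability** — pre/post-blockade comparison (one-tailed Wilcoxon
  signed-rank on per-scan median similarity), per-subject test-retest
  Spearman, edgewise ICC(3,1), and retest identification accuracy;
- **classification** — one-vs-all and multiclass L1 logistic regression
  with leakage-safe residualization, repeated stratified k-fold CV for the
  penalty, AP / ROC-AUC with bootstrap CIs, per-region importance scores,
  and coefficient-overlap correlations; covariate-predictability probes
  (elastic-net LR, KNN, SVM);
- **fingerprinting** — nearest-neighbour diagnostic assignment by maximal
  Spearman correlation between edge vectors, with confusion matrix,
  balanced accuracy and per-group recall;
- **synthetic** — a deterministic multi-site dynamic-PET cohort simulator
  (tri-exponential bolus input, irreversible kinetics, frame averaging,
  count-statistics noise, batch/covariate/disease effects, retest and
  blockade sessions) plus a fast edge-level generator for power and null
  studies. All analyses are exercised end-to-end against this simulator.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (Monte-Carlo
power/null studies; a few minutes on one CPU); the rest of the suite runs
in under a minute.

## CLI

```bash
netfp simulate --out-dir cohort/ --seed 7                 # demo cohort
netfp simulate --design examples/design.yaml --out-dir cohort/ --seed 7
netfp features --manifest cohort/manifest.json --out features.tsv
netfp network  --manifest cohort/manifest.json --out-dir net/
netfp harmonize --manifest cohort/manifest.json --edges net/edges.tsv --out-dir harm/
netfp reliability --manifest cohort/manifest.json --mode testretest --out rel.json
netfp classify --manifest cohort/manifest.json --edges net/edges.tsv \
               --disease MS --seed 7 --out ms.json
netfp fingerprint --manifest cohort/manifest.json --edges net/edges.tsv \
                  --corrected --out fp.json
netfp run-all --out-dir run/ --seed 7                     # full workflow
```

`run-all` also accepts a YAML run config (`--config cfg.yaml`); every JSON
report embeds the config hash and package version, and identical
config+seed runs produce byte-identical reports.

## File formats (all plain text)

- TAC table: TSV `scan_id, roi, frame_index, activity_kBq_per_mL`
- manifest: JSON (covariates, frame schedule in minutes, IDIF paths)
- IDIF: TSV `time_min, concentration_kBq_per_mL`
- similarity matrices: TSV with ROI-name header row/column
- edge tables: TSV, rows = scans, columns = `roi_i|roi_j` in canonical
  upper-triangle order (3741 edges for 87 regions)

Input contract: TACs are assumed decay-corrected; no decay correction is
applied anywhere in the package.
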