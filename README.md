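# cxragree

Diagnostic-accuracy evaluation of paired readers against a reference
standard, built for reader studies of trauma chest radiographs in which a
reporting radiologist and a commercial deep-learning algorithm each call a
set of findings (pneumothorax, rib / clavicle / humerus / scapula fracture,
lobar or segmental collapse, pneumomediastinum) and the report of a
contemporaneous CT provides the ground truth. It is aimed at researchers
running external validations of radiology AI who need the full statistical
pipeline but not the images.

## What it computes

For each finding and reader, with 2×2 counts (TP, FP, FN, TN) against truth:

- **Sensitivity** TP/(TP+FN) and **specificity** TN/(TN+FP), with exact
  Clopper–Pearson 95% intervals (equal-tailed inversion of the binomial
  tails, computed as beta quantiles).
- **Cohen's κ** = (p_o − p_e)/(1 − p_e), the chance-corrected agreement of
  the reader with the reference standard, with either a large-sample
  (Fleiss–Cohen–Everitt) or a percentile-bootstrap interval.
- **Paired bootstrap** for Δκ = κ_B − κ_A: cases are resampled with
  replacement, both readers' calls travelling with their case, preserving
  the within-case correlation of the readers; reported as the bootstrap
  median, 2.5th/97.5th percentiles and a two-sided p-value by interval
  inversion (p ≤ 0.05 exactly when the 95% percentile interval excludes 0).
- **Hybrid (OR-rule) reader**: a finding counts as called when either
  reader calls it — the "radiologist with AI assistance" operating point.
  Its sensitivity can only rise and its specificity only fall relative to
  the component readers.
- **ROC/AUC** for score-bearing readers (Mann–Whitney AUC, ties counted
  half).

A reader call may also be *unavailable* (the algorithm failed to process an
image); policies `drop` (shrink the denominator) and `count_negative`
(treat failure as a miss) are explicit everywhere.

A synthetic-cohort generator (`SimulationConfig`, `simulate_dataset`)
produces paired-reader data with configured prevalence, per-reader
operating points, inter-reader dependence conditional on truth (a
common-shock mixture with closed-form joint cells, hence a closed-form
generator-implied κ), algorithm failure rates and binormal confidence
scores — so the whole pipeline is testable end to end without any images.

## Worked example

Simulate a cohort matching the packaged study's pneumothorax row
(n = 1404, prevalence 12.3%, radiologist 33.1%/99.4%, AI 39.2%/99.8%,
≈0.3% AI failures), then run the paired comparison:

```sh
$ cat pneumo.yaml
n_cases: 1404
prevalence: 0.123
se_a: 0.331
sp_a: 0.994
se_b: 0.392
sp_b: 0.998
dep_pos: 0.3
dep_neg: 0.1
failure_rate_b: 0.00285
seed: 7

$ cxragree simulate --config pneumo.yaml --out pneumo.csv
wrote 1404 records to pneumo.csv

$ cxragree compare --input pneumo.csv --n-boot 10000 --seed 42
pneumothorax: delta_kappa median +0.077 (-0.024 to 0.177), p = 0.1426 [n=1402, n_boot=10000, seed=42, degenerate=0]
```

The AI's configured sensitivity advantage shows up as a positive median
Δκ of 0.077, but at a single simulated cohort of this size the 95%
percentile interval still crosses zero (p = 0.14): a κ difference of this
magnitude is near the edge of what n ≈ 1400 can resolve. Two cases were
dropped because the simulated AI produced no output for them
(`n=1402` under the default intersection pairing policy).

Analysing the packaged study tables reproduces the published accuracy
table; e.g. the pneumothorax rows of `report.md`:

```sh
$ cxragree analyze --fixture --outdir report --quiet
```

| finding | reader | tp | fp | fn | tn | sensitivity % (CI) | specificity % (CI) | kappa (CI) |
|---|---|---|---|---|---|---|---|---|
| pneumothorax | radiologist | 57 | 8 | 115 | 1224 | 33.1 (26.2-40.7) | 99.4 (98.7-99.7) | 0.44 (0.36-0.52) |
| pneumothorax | ai | 67 | 2 | 104 | 1227 | 39.2 (31.8-46.9) | 99.8 (99.4-100.0) | 0.52 (0.45-0.60) |

The same objects are available as a library:

```python
from cxragree import study_confusion_tables, cohens_kappa, sensitivity

ct = study_confusion_tables()[("pneumothorax", "radiologist")]
print(round(cohens_kappa(ct).kappa, 2))   # 0.44
print(str(sensitivity(ct)))               # 33.1% (26.2-40.7)
```

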