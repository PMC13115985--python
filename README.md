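# cecdx

Diagnostic accuracy of circulating endometrial cell (CEC) detection for
endometriosis **without a gold standard**: constrained latent class models,
covariate-varying accuracy curves, latent-status imputation, and full-pipeline
bootstrap inference — plus a synthetic-cohort generator and a CLI.

## The problem

Endometriosis lacks a perfect diagnostic reference. Laparoscopy, the usual
comparator, misses lesions (false negatives), so naively cross-tabulating a
new biomarker against laparoscopy biases its estimated sensitivity and
specificity. This package evaluates a three-test panel — laparoscopy, CEC
detection (positive at ≥ 1 cell / 6 mL), and serum CA125 (≥ 35 U/mL) — by
treating disease status as latent.

## The model

Each patient has an unobserved status `D ~ Bernoulli(π)`. Given `D`, the
binary test results are conditionally independent with per-test sensitivity
`Se_k` and specificity `Sp_k` (the Hui–Walter two-class latent class model):

```
P(y) = π Π_k Se_k^{y_k}(1−Se_k)^{1−y_k}  +  (1−π) Π_k (1−Sp_k)^{y_k} Sp_k^{1−y_k}
```

Estimation is by constrained EM on collapsed response patterns. The default
constraint fixes laparoscopy **specificity** at 1 (a visualized lesion is not
a false positive) while leaving its **sensitivity** free — the quantity a
gold-standard analysis cannot estimate. Label switching is resolved by
requiring the anchor test's Youden index to be non-negative. Accuracy that
varies with pain intensity is estimated by kernel-weighted local likelihood
over the VAS 0–10 scale; pooled Se/Sp point estimates come from latent-status
imputation, and every confidence interval is a percentile bootstrap that
refits the entire pipeline per patient resample. See
[`docs/methods.md`](docs/methods.md) for the full treatment and the rationale
behind every default.

## Worked example (Python)

```python
from cecdx import scenario_preset, simulate_cohort, build_test_panel, fit_em

config = scenario_preset("overall", n=2000, seed=1)
cohort, truth = simulate_cohort(config)   # truth carries the latent statuses
panel = build_test_panel(cohort)
fit = fit_em(panel, seed=0)               # laparoscopy Sp fixed at 1 by default
for name, value in fit.params.as_dict().items():
    print(f"{name:18s} {value:.3f}")
```

Output:

```
prevalence         0.502
se_laparoscopy     0.866
sp_laparoscopy     1.000
se_CEC             0.571
sp_CEC             0.812
se_CA125           0.367
sp_CA125           0.747
```

The generating values were π = 0.48, laparoscopy (0.88, 1.00), CEC
(0.58, 0.81), CA125 (0.37, 0.754).

## Worked example (CLI)

```sh
cecdx simulate --preset overall --n 300 --seed 42 --out cohort.csv
cecdx fit --cohort cohort.csv --seed 42 --bootstrap-B 200 \
          --imputations-M 50 --out-prefix overall
```

prints the study-style accuracy table (and writes `overall.table.csv`,
`overall.table.txt`, `overall.fit.json`):

```
overall
  laparoscopy  sensitivity  0.98 (0.61, 1.00)
  laparoscopy  specificity  1.00 (1.00, 1.00)
  CEC          sensitivity  0.50 (0.42, 0.59)
  CEC          specificity  0.77 (0.72, 1.00)
  CA125        sensitivity  0.37 (0.30, 0.46)
  CA125        specificity  0.74 (0.68, 0.85)
```

Note the pinned parameter's degenerate interval `1.00 (1.00, 1.00)` — the
structural constraint survives every bootstrap resample. Other commands:

```sh
cecdx describe --cohort cohort.csv --by vas --out vas.csv     # detection rates
cecdx curves --cohort cohort.csv --seed 7 --bandwidth 1.5 \
             --out-prefix curves                              # VAS-varying accuracy
```

Every command is bit-reproducible under a fixed seed; logs go to stderr,
results to files.

## Package layout

| Module | Contents |
|---|---|
| `cecdx.records` | Patient records, classification rules, cohort CSV I/O, test panels |
| `cecdx.simulate` | Synthetic-cohort generator and scenario presets |
| `cecdx.lca` | Constrained EM for the two-class latent class model |
| `cecdx.curves` | Kernel-weighted local-likelihood accuracy curves over VAS |
| `cecdx.inference` | Latent-status imputation, percentile bootstrap, accuracy tables |
| `cecdx.descriptives` | Detection rates, stratified summaries, subtype proportions |
| `cecdx.cli` | `cecdx simulate / fit / curves / describe` |
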