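# Methods

This note records the statistical model, the estimation machinery, the
synthetic-cohort generator, and the reasoning behind every default the
package ships with.

## 1. Problem setting

Circulating endometrial cells (CECs) are a candidate blood biomarker for
endometriosis. Evaluating them is complicated by the absence of a perfect
reference: laparoscopy, the usual clinical comparator, is itself imperfect
(false negatives occur), so cross-tabulating CEC results against laparoscopy
would misstate both sensitivity and specificity. The package therefore
estimates the accuracy of a three-test panel — laparoscopy, CEC detection
(positive at ≥ 1 cell per 6 mL of blood), and serum CA125 (positive at
≥ 35 U/mL, threshold inclusive) — *without* assuming any test is a gold
standard.

## 2. Latent class model

### 2.1 Structure

Each patient carries an unobserved disease status `D ∈ {0, 1}` with
prevalence `π = P(D = 1)`. Given `D`, the `K` binary test results
`Y_1, …, Y_K` are assumed conditionally independent, with per-test
sensitivity `Se_k = P(Y_k = 1 | D = 1)` and specificity
`Sp_k = P(Y_k = 0 | D = 0)` (the Hui–Walter two-class model). The
observed-data likelihood of a response pattern `y` is

```
P(y) = π · Π_k Se_k^{y_k} (1−Se_k)^{1−y_k}
     + (1−π) · Π_k (1−Sp_k)^{y_k} Sp_k^{1−y_k}
```

with missing results (e.g., no surgical evaluation) simply dropped from the
product — missingness is assumed ignorable given `D`.

### 2.2 Constraints and identifiability

With three tests the unconstrained model (7 parameters) is just identified,
but two issues remain: label switching (the mirrored parameterization
`π → 1−π`, `Se ↔ 1−Sp` has the same likelihood) and the near-flat ridge
between prevalence and the reference test's sensitivity. The default
constraint set (`ConstraintSpec.default("laparoscopy")`) fixes laparoscopy
specificity at 1 — a surgically visualized lesion is not a false positive —
while leaving its *sensitivity* free, which is precisely the quantity a
gold-standard analysis cannot estimate. Labels are resolved by requiring the
anchor test's Youden index (`Se + Sp − 1`) to be non-negative; the swap is
suppressed if it would violate a hard constraint.

A consequence of `Sp_lap = 1`: any laparoscopy-positive patient has posterior
disease probability exactly 1, and bootstrap intervals for the pinned
parameter are degenerate — the tables legitimately print `1.00 (1.00, 1.00)`.

With fewer than three tests and no constraints the model is not
identifiable; the fit proceeds but is flagged (`non_identifiable`), never
silently.

### 2.3 EM algorithm

Estimation is by EM on *collapsed response patterns*: the at most `3^K`
distinct observed patterns (positive / negative / missing per test) are
aggregated with multiplicity (or kernel) weights, so per-iteration cost is
independent of cohort size. The E-step computes pattern posteriors by Bayes'
rule; the M-step takes responsibility-weighted averages and then overwrites
constrained entries. Convergence is declared when the relative
log-likelihood change falls below `tol = 1e-8`; the reported log-likelihood
is evaluated at the returned parameters. An empty latent class (total
responsibility zero, possible under degenerate inputs) raises
`EmptyClassError` rather than returning 0/0 artifacts.

Multimodality is handled by restarts: one informed start (cross-tabulation
against the anchor test) plus uniform-random starts, `n_restarts = 20` by
default; the best likelihood wins. All randomness flows through an explicit
seed, so fits are bit-reproducible.

The inner loop is JIT-compiled with numba when available, with a pure-Python
fallback; an independently written vectorized NumPy implementation
(`_em_run_reference`) is retained and cross-checked in the test suite to
~1e-10 agreement.

## 3. Covariate-varying accuracy (local likelihood)

Test accuracy may vary with dysmenorrhea intensity (VAS 0–10). Rather than
slicing into coarse strata, `curves.fit_curve` fits the latent class model
at each point `v0` of a VAS grid (default 0 to 10 in steps of 0.25, i.e., 41
points) using kernel weights `K((v_i − v0)/h)` — Gaussian by default,
Epanechnikov available. This is local-likelihood estimation: each grid point
gets its own constrained EM fit on the weighted patterns, warm-started from
the neighbouring grid point.

* **Effective sample size.** `eff_n(v0) = Σ_i w_i`. Points with `eff_n < 10`
  are still estimated but flagged; the floor of 10 is roughly the smallest
  count at which a 7-parameter mixture fit is ever meaningful.
* **Bandwidth.** Default `h = 1.5` VAS units (about one severity band).
  `select_bandwidth` offers Silverman's rule `1.06 · sd(VAS) · n^(−1/5)`
  and leave-one-out cross-validated likelihood over a log-spaced candidate
  grid (held-out evaluation subsampled to 100 patients for tractability).
* **Limits.** As `h → ∞` all weights tend to 1 and every local fit equals
  the homogeneous fit — a property the tests enforce to 1e-6.
* **Bands.** Pointwise 95% bands bootstrap patients and refit the whole
  curve per replicate (percentile method).

## 4. Pooled inference: imputation and bootstrap

Because no perfect reference exists, Se/Sp point estimates are produced by
**latent-status imputation**: draw `D_i ~ Bernoulli(γ_i)` from the fitted
posteriors `M = 50` times, cross-tabulate each test against the imputed
statuses, and average. `M = 50` makes the Monte Carlo error of the averaged
estimate well below 0.01 (verified against `M = 500`). With degenerate
posteriors (`γ ∈ {0, 1}`) this reduces exactly to a cross-tabulation.

Every confidence interval is a **percentile bootstrap over patients**
(`B = 1000` by default): resample the cohort with replacement (optionally
within strata, preserving stratum sizes), rerun the *entire* estimator —
EM fit plus imputation — on each replicate, and take the 2.5/97.5
percentiles. Replicates on which the estimator fails are dropped and logged;
more than 10% failures aborts the interval rather than returning a
misleading one. Bootstrap refits are warm-started at the full-data estimate,
which changes nothing asymptotically but cuts the iteration count sharply.

`accuracy_report` assembles the study-style table: per stratum
(dysmenorrhea band, lesion activity, or pooled menstrual phase), per test,
`estimate (lo, hi)`; strata smaller than 15 patients are estimated but
flagged.

## 5. Classification rules

* CEC positive ⇔ count ≥ 1 per 6 mL.
* CA125 positive ⇔ value ≥ 35 U/mL (inclusive).
* Dysmenorrhea bands: VAS 0 = none, 1–3 = mild, 4–6 = moderate,
  7–10 = severe; fractional scores round half-up to the nearest integer
  before banding.
* Lesion activity: *active* ⇔ symptoms worsened over the last 6 months
  **and** VAS ≥ 6 (threshold configurable); otherwise dormant.
* Menstrual phases: menstrual and proliferative are pooled (hormonally
  adjacent and individually small), secretory kept separate.

## 6. Synthetic-cohort generator

No patient-level data are distributed; everything runs on synthetic cohorts
drawn from `CohortConfig`, which makes the generating truth available for
recovery testing.

* **Disease status** `D_i ~ Bernoulli(π)`; prevalence may be a constant or a
  function of VAS and phase.
* **Test results** are drawn conditionally independently given `D_i` from
  `(Se_k, Sp_k)` — i.e., the generator matches the model's dependence
  structure, which is exactly what parameter-recovery tests require.
* **CEC counts** follow a hurdle model: the binary layer is authoritative
  (count ≥ 1 iff the binary CEC result is positive), with positive counts
  zero-truncated Poisson, mean parameter 3.0 for diseased and 1.5 for
  false-positive patients. These choices give overall mean counts near the
  observed ~2.4 cells/6 mL in disease and ~0.9 in controls.
* **VAS** is a mixture: a point mass at 0 (probability 0.47, matching the
  observed share of pain-free patients) and a Beta(1.0, 1.8) discretized
  onto 1–10 otherwise — right-skewed, as pain scores are.
* **Phases** are drawn with probabilities (0.07, 0.40, 0.53) for menstrual,
  proliferative, secretory.
* **Treatment** (GnRHa) multiplies the odds of CEC detection in diseased
  patients by 0.156 — the exact odds ratio mapping a 64.0% detection rate to
  21.7% — so the treated preset reproduces the observed suppression.
* **Subtype counts** split each patient's CEC count binomially into small
  (< 5 µm) and large cells, with small-cell fractions 0.7406 (untreated
  disease), 0.125 (treated), 0.0495 (controls).
* **Seeding**: a single integer seed is fanned out through
  `np.random.SeedSequence.spawn` into independent streams per component, so
  adding a component never perturbs another's draws.

**Scenario presets** bundle generating parameters for the overall cohort and
for strata defined by dysmenorrhea severity, lesion activity, menstrual
phase, and treatment, using published point estimates for a CEC / CA125 /
laparoscopy panel as the generating truths. Prevalences not derivable from
printed counts (within-VAS-band and within-phase strata) are set to the
overall 0.48 — an explicit assumption, configurable per preset; the activity
strata use 18/35 (active) and 67/194 (dormant).

### Generator limitations

The generator is deliberately faithful to the *model*, not to every clinical
nuance: conditional independence holds exactly (no shared-mechanism
correlation between CEC and CA125), accuracy is constant within a preset
(covariate-varying truths are constructed directly in the tests that need
them), and CA125 values are drawn from simple parametric shapes around the
threshold. It is a testbed for the estimators, not a patient simulator.

## 7. Numerical and testing choices

* Pattern collapsing bounds EM cost by distinct patterns (≤ 27 for three
  tests), so `n = 2000` cohorts, kernel-weighted fits, and thousands of
  bootstrap refits are all cheap.
* Problem sizes used in the test suite — cohorts of 2000 for recovery (20
  seeds, tolerance ±0.05 on all free parameters), `B = 200` bootstrap
  replicates with 200 outer replications for the coverage check (95% ± 4),
  100 random fixtures for EM monotonicity, a 21³ grid-search oracle at
  n = 60 — were chosen so each suite runs in minutes on one CPU while
  keeping Monte Carlo error well inside the asserted tolerances.
* Recovery caveat: with `Sp_lap` fixed at 1, laparoscopy sensitivity and
  prevalence are separated only by the weaker CEC/CA125 signal, so the ML
  estimator of `Se_lap` at n = 2000 has a standard deviation near 0.09.
  Averages over 20 cohorts therefore carry a standard error of ~0.02, and a
  rare unlucky seed block can fall outside a ±0.05 band; this is sampling
  variation, not estimator failure (verified over 300 Monte Carlo fits:
  mean 0.872–0.886 against a generating value of 0.88).
* One printed-rate caveat: a detection rate of 36/146 equals 24.6575…%,
  which rounds to **24.7%** at one decimal; the package renders the correct
  rounding of the exact fraction.
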