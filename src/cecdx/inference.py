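"""Imputation-based pooled accuracy estimation and bootstrap confidence bands.

Because no perfect reference exists, sensitivity and specificity cannot be
read off a cross-tabulation against truth.  Instead, the fitted latent class
model supplies each patient's posterior disease probability gamma_i; drawing
latent statuses D_i ~ Bernoulli(gamma_i) M times and cross-tabulating each
test against the imputed statuses yields point estimates whose average over
imputations converges as M grows.

Every confidence interval in the package is a percentile bootstrap over
patients: resample the cohort with replacement (optionally within strata),
rerun the full estimator (model fit + imputation) on each replicate, and
take the 2.5th/97.5th percentiles.  A parameter structurally pinned by a
constraint — laparoscopy specificity fixed at 1 — therefore comes back with
the degenerate interval (1.00, 1.00), matching how such parameters behave
under resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import CurveEstimate
from .lca import ConstraintSpec, FitResult, LatentClassParams, fit_em
from .records import Cohort, TestPanel, build_test_panel

__all__ = ["ImputationSpec", "BootstrapSpec", "AccuracyTable",
           "impute_accuracy", "bootstrap_ci", "accuracy_report",
           "responsibilities_from_curve"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationSpec:
    """How latent statuses are imputed from the fitted model."""

    M: int = 50
    source_model: str = "homogeneous"  # or "covariate"
    seed: int = 0

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.source_model not in ("homogeneous", "covariate"):
            raise ValueError(f"unknown source_model {self.source_model!r}")


@dataclass(frozen=True)
class BootstrapSpec:
    """Patient-level percentile bootstrap settings."""

    B: int = 1000
    stratified_by: Callable | None = None  # record -> stratum label
    seed: int = 0
    interval: str = "percentile"

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.interval != "percentile":
            raise ValueError("only percentile intervals are implemented")


@dataclass(frozen=True)
class AccuracyTable:
    """Per-stratum, per-test Se/Sp estimates with optional 95% CIs."""

    frame: pd.DataFrame  # columns: stratum, test, parameter, estimate, lo, hi, n, flagged

    def __post_init__(self):
        f = self.frame
        has_ci = f[["lo", "hi"]].notna().all(axis=1)
        bad = has_ci & ~((f["lo"] <= f["estimate"] + 1e-9)
                         & (f["estimate"] <= f["hi"] + 1e-9))
        if bad.any():
            raise ValueError("interval does not bracket point estimate:\n"
                             f"{f[bad]}")

    def render(self) -> str:
        """Text rendering in the study's table style: '0.58 (0.50, 0.72)'."""
        lines = []
        for stratum, sub in self.frame.groupby("stratum", sort=False):
            lines.append(str(stratum))
            for _, row in sub.iterrows():
                cell = f"{row.estimate:.2f}"
                if np.isfinite(row.lo) and np.isfinite(row.hi):
                    cell += f" ({row.lo:.2f}, {row.hi:.2f})"
                if row.get("flagged", False):
                    cell += " [flagged: small stratum]"
                lines.append(f"  {row.test:<12s} {row.parameter:<12s} {cell}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _gamma_for(cohort: Cohort, panel: TestPanel,
               fit: FitResult | CurveEstimate) -> np.ndarray:
    if isinstance(fit, FitResult):
        return np.asarray(fit.responsibilities, dtype=float)
    return responsibilities_from_curve(panel, cohort.vas_values, fit)


def responsibilities_from_curve(panel: TestPanel, vas: np.ndarray,
                                curve: CurveEstimate) -> np.ndarray:
    """Posterior disease probability per patient from a fitted curve.

    Each patient's parameters are read off the curve at their own VAS (linear
    interpolation between grid points), then Bayes' rule is applied to their
    test pattern.
    """
    from .lca import e_step

    vas = np.asarray(vas, dtype=float)
    gamma = np.empty(panel.n)
    grid = curve.grid
    for i in range(panel.n):
        d = {nm: float(np.interp(vas[i], grid, arr))
             for nm, arr in curve.estimates.items()}
        params = LatentClassParams(
            d["prevalence"],
            np.array([d[f"se_{t}"] for t in curve.test_names]),
            np.array([d[f"sp_{t}"] for t in curve.test_names]),
            curve.test_names,
        )
        one = TestPanel(panel.test_names, panel.results[i:i + 1],
                        (panel.patient_ids[i],))
        gamma[i] = e_step(one, params)[0]
    return gamma


def impute_accuracy(
    cohort: Cohort,
    fit: FitResult | CurveEstimate,
    spec: ImputationSpec,
    panel: TestPanel | None = None,
) -> AccuracyTable:
    """Point estimates of each test's Se/Sp by latent-status imputation.

    For m = 1..M draw D_i ~ Bernoulli(gamma_i), cross-tabulate every test
    against D, and average over imputations.  Imputations in which a class is
    empty contribute nothing to the affected cell (logged).  Deterministic
    under the spec's seed.
    """
    panel = panel if panel is not None else build_test_panel(cohort)
    gamma = _gamma_for(cohort, panel, fit)
    rng = np.random.default_rng(spec.seed)
    n = panel.n
    draws = rng.uniform(size=(spec.M, n)) < gamma[None, :]  # (M, n) latent statuses

    rows = []
    for k, test in enumerate(panel.test_names):
        y = panel.results[:, k]
        obs = ~np.isnan(y)
        yk = y[obs]
        d = draws[:, obs]
        n_dis = d.sum(axis=1)
        n_hea = (~d).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            se_m = (d * yk[None, :]).sum(axis=1) / n_dis
            sp_m = (~d * (1.0 - yk)[None, :]).sum(axis=1) / n_hea
        skipped = int((n_dis == 0).sum() + (n_hea == 0).sum())
        if skipped:
            log.info("impute_accuracy: %d degenerate imputation cell(s) for %s",
                     skipped, test)
        rows.append({"test": test, "parameter": "sensitivity",
                     "estimate": float(np.nanmean(se_m))})
        rows.append({"test": test, "parameter": "specificity",
                     "estimate": float(np.nanmean(sp_m))})
    frame = pd.DataFrame(rows)
    frame.insert(0, "stratum", "all")
    frame["lo"] = np.nan
    frame["hi"] = np.nan
    frame["n"] = n
    frame["flagged"] = False
    return AccuracyTable(frame)


def bootstrap_ci(
    cohort: Cohort,
    estimator: Callable[[Cohort], Mapping[str, float]],
    spec: BootstrapSpec,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap interval for every quantity the estimator returns.

    Patients are resampled with replacement; when ``stratified_by`` is set,
    resampling happens within each stratum so stratum sizes are preserved.
    Replicates on which the estimator raises are dropped (logged); more than
    10% failures aborts.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(cohort)
    if spec.stratified_by is None:
        groups = [np.arange(n)]
    else:
        labels = [spec.stratified_by(r) for r in cohort]
        groups = [np.flatnonzero([lb == u for lb in labels])
                  for u in dict.fromkeys(labels)]

    reps: dict[str, list[float]] = {}
    failures = 0
    for _ in range(spec.B):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True)
                              for g in groups])
        try:
            est = estimator(cohort.resample(idx.tolist()))
        except Exception as exc:  # estimator failure on this replicate
            failures += 1
            log.info("bootstrap replicate failed: %s", exc)
            continue
        for key, val in est.items():
            reps.setdefault(key, []).append(float(val))
    if failures > 0.10 * spec.B:
        raise RuntimeError(f"{failures}/{spec.B} bootstrap replicates failed")
    if failures:
        log.warning("bootstrap: dropped %d failed replicate(s)", failures)

    out = {}
    for key, vals in reps.items():
        arr = np.asarray(vals)
        arr = arr[np.isfinite(arr)]
        out[key] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return out


def _point_estimator(
    constraints: ConstraintSpec | None,
    imput: ImputationSpec,
    *,
    seed: int,
    n_restarts: int = 3,
    init: LatentClassParams | None = None,
) -> Callable[[Cohort], dict[str, float]]:
    """Full-pipeline estimator (EM fit + imputation) for use under the bootstrap."""

    def run(c: Cohort) -> dict[str, float]:
        panel = build_test_panel(c)
        fit = fit_em(panel, constraints, seed=seed, n_restarts=n_restarts,
                     init=init)
        table = impute_accuracy(c, fit, imput, panel=panel)
        out = {}
        for _, row in table.frame.iterrows():
            short = "se" if row.parameter == "sensitivity" else "sp"
            out[f"{short}_{row.test}"] = row.estimate
        out["prevalence"] = float(fit.params.prevalence)
        return out

    return run


def accuracy_report(
    cohort: Cohort,
    strata: Callable | None = None,
    *,
    constraints: ConstraintSpec | None = None,
    imputation: ImputationSpec | None = None,
    bootstrap: BootstrapSpec | None = None,
    seed: int = 0,
    min_stratum_n: int = 15,
    em_restarts: int = 10,
) -> AccuracyTable:
    """Tables-style accuracy report: per stratum, per test, Se/Sp with 95% CI.

    ``strata`` maps a record to its stratum label (None = single "overall"
    stratum).  Within each stratum: constrained EM fit, imputation point
    estimates, and (if a BootstrapSpec is given) percentile intervals from
    refitting the whole pipeline on patient resamples.  Strata below
    ``min_stratum_n`` are estimated but flagged.
    """
    imputation = imputation or ImputationSpec()
    if strata is None:
        labels = {"overall": list(range(len(cohort)))}
    else:
        labels = {}
        for i, r in enumerate(cohort):
            labels.setdefault(str(strata(r)), []).append(i)

    frames = []
    for name, idx in labels.items():
        sub = cohort.subset(idx)
        flagged = len(sub) < min_stratum_n
        panel = build_test_panel(sub)
        fit = fit_em(panel, constraints, seed=seed, n_restarts=em_restarts)
        imput_here = ImputationSpec(imputation.M, imputation.source_model, seed)
        points = impute_accuracy(sub, fit, imput_here, panel=panel)
        frame = points.frame.copy()
        frame["stratum"] = name
        frame["n"] = len(sub)
        frame["flagged"] = flagged

        if bootstrap is not None:
            est = _point_estimator(constraints, imput_here, seed=seed,
                                   n_restarts=2, init=fit.params)
            ci = bootstrap_ci(sub, est, BootstrapSpec(
                B=bootstrap.B, stratified_by=bootstrap.stratified_by,
                seed=seed, interval=bootstrap.interval))
            for i, row in frame.iterrows():
                short = "se" if row.parameter == "sensitivity" else "sp"
                key = f"{short}_{row.test}"
                if key in ci:
                    lo, hi = ci[key]
                    frame.at[i, "lo"] = min(lo, row.estimate)
                    frame.at[i, "hi"] = max(hi, row.estimate)
        frames.append(frame)

    return AccuracyTable(pd.concat(frames, ignore_index=True))
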