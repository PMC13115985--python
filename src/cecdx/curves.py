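"""Covariate-varying latent class estimation: accuracy as a function of VAS.

Prevalence and each test's sensitivity/specificity are allowed to vary
smoothly with the VAS pain score within a (pooled) menstrual-cycle-phase
stratum.  Estimation is local-likelihood EM: at a target score v0, every
patient's likelihood contribution is weighted by a kernel in the distance
between their VAS and v0, and the weighted EM of :mod:`cecdx.lca` is run.
Sweeping v0 over a grid yields the sensitivity/specificity curves, with
pointwise percentile-bootstrap bands obtained by resampling patients and
refitting the whole curve.

With the bandwidth taken to infinity all weights become equal and every local
fit collapses to the homogeneous model — the anchor property the test suite
checks on every fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lca import ConstraintSpec, FitResult, LatentClassParams, fit_em
from .records import TestPanel

__all__ = ["KernelSpec", "LocalFit", "CurveEstimate", "local_fit",
           "fit_curve", "select_bandwidth", "DEFAULT_GRID"]

DEFAULT_GRID = np.round(np.arange(0.0, 10.0 + 1e-9, 0.25), 2)
DEFAULT_EFF_N_FLOOR = 10.0


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing kernel and bandwidth (in VAS units)."""

    kernel: str = "gaussian"  # or "epanechnikov"
    bandwidth: float = 1.5
    bandwidth_rule: str = "fixed"  # "fixed" | "silverman" | "cv"

    def __post_init__(self):
        if self.kernel not in ("gaussian", "epanechnikov"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    def weights(self, vas: np.ndarray, v0: float) -> np.ndarray:
        """Unnormalized kernel weights, 1 at zero distance."""
        z = (np.asarray(vas, dtype=float) - v0) / self.bandwidth
        if self.kernel == "gaussian":
            return np.exp(-0.5 * z * z)
        return np.maximum(0.0, 1.0 - z * z)


@dataclass(frozen=True)
class LocalFit:
    """Local EM estimate at one VAS value."""

    v0: float
    params: LatentClassParams
    loglik: float
    eff_n: float
    flagged: bool  # effective sample size below the floor


@dataclass(frozen=True)
class CurveEstimate:
    """Accuracy curves over a VAS grid within one phase stratum.

    ``estimates`` / ``lo`` / ``hi`` map parameter names (``prevalence``,
    ``se_<test>``, ``sp_<test>``) to arrays over the grid; bands are NaN when
    no bootstrap was run or a point was flagged.
    """

    stratum: str
    grid: np.ndarray
    estimates: dict[str, np.ndarray]
    lo: dict[str, np.ndarray]
    hi: dict[str, np.ndarray]
    eff_n: np.ndarray
    flagged: np.ndarray
    test_names: tuple[str, ...]

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        if ((g < 0) | (g > 10)).any():
            raise ValueError("grid must lie within [0, 10]")
        for name, est in self.estimates.items():
            lo, hi = self.lo.get(name), self.hi.get(name)
            if lo is not None and hi is not None:
                ok = np.isnan(lo) | np.isnan(hi) | ((lo <= est + 1e-9) & (est <= hi + 1e-9))
                if not ok.all():
                    raise ValueError(f"CI band does not bracket estimate for {name}")

    def to_frame(self) -> pd.DataFrame:
        """Long format: stratum, vas, test, parameter, estimate, lo, hi, eff_n."""
        rows = []
        for name, est in self.estimates.items():
            if name == "prevalence":
                test, parameter = "", "prevalence"
            else:
                parameter, test = name.split("_", 1)
            lo = self.lo.get(name, np.full_like(est, np.nan))
            hi = self.hi.get(name, np.full_like(est, np.nan))
            for j, v in enumerate(self.grid):
                rows.append({
                    "stratum": self.stratum, "vas": float(v), "test": test,
                    "parameter": parameter, "estimate": float(est[j]),
                    "lo": float(lo[j]), "hi": float(hi[j]),
                    "eff_n": float(self.eff_n[j]), "flagged": bool(self.flagged[j]),
                })
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def local_fit(
    panel: TestPanel,
    vas: np.ndarray,
    v0: float,
    kernel: KernelSpec,
    constraints: ConstraintSpec | None = None,
    *,
    seed: int,
    n_restarts: int = 5,
    eff_n_floor: float = DEFAULT_EFF_N_FLOOR,
    init: LatentClassParams | None = None,
) -> LocalFit:
    """Kernel-weighted EM estimate of the latent class model at VAS = v0.

    The effective sample size is the sum of kernel weights; below
    ``eff_n_floor`` the estimate is still returned but flagged, never silent.
    """
    vas = np.asarray(vas, dtype=float)
    if vas.shape != (panel.n,):
        raise ValueError("vas must have one entry per patient")
    w = kernel.weights(vas, float(v0))
    eff_n = float(w.sum())
    flagged = eff_n < eff_n_floor
    fit = fit_em(panel, constraints, weights=w, seed=seed,
                 n_restarts=n_restarts, init=init)
    return LocalFit(v0=float(v0), params=fit.params, loglik=fit.loglik,
                    eff_n=eff_n, flagged=flagged)


def _curve_points(panel, vas, grid, kernel, constraints, seed, n_restarts,
                  eff_n_floor):
    fits = []
    prev_init = None
    for v0 in grid:
        lf = local_fit(panel, vas, v0, kernel, constraints, seed=seed,
                       n_restarts=n_restarts, eff_n_floor=eff_n_floor,
                       init=prev_init)
        prev_init = lf.params  # warm-start the neighbouring grid point
        fits.append(lf)
    return fits


def fit_curve(
    panel: TestPanel,
    vas: np.ndarray,
    stratum: str,
    grid: Sequence[float] | None = None,
    kernel: KernelSpec | None = None,
    constraints: ConstraintSpec | None = None,
    *,
    seed: int,
    bootstrap_B: int = 0,
    n_restarts: int = 5,
    eff_n_floor: float = DEFAULT_EFF_N_FLOOR,
) -> CurveEstimate:
    """Accuracy curves on a VAS grid, with optional pointwise bootstrap bands.

    Bands (``bootstrap_B`` > 0) resample patients with replacement and refit
    the entire curve per replicate; the 2.5/97.5 percentiles of each
    parameter at each grid point form the 95% interval.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    kernel = kernel or KernelSpec()
    fits = _curve_points(panel, vas, grid, kernel, constraints, seed,
                         n_restarts, eff_n_floor)
    names = ["prevalence"] + [f"se_{t}" for t in panel.test_names] \
        + [f"sp_{t}" for t in panel.test_names]
    est = {nm: np.array([lf.params.as_dict()[nm] for lf in fits]) for nm in names}
    eff_n = np.array([lf.eff_n for lf in fits])
    flagged = np.array([lf.flagged for lf in fits])

    lo = {nm: np.full(len(grid), np.nan) for nm in names}
    hi = {nm: np.full(len(grid), np.nan) for nm in names}
    if bootstrap_B > 0:
        rng = np.random.default_rng(seed)
        reps = {nm: np.empty((bootstrap_B, len(grid))) for nm in names}
        n = panel.n
        for b in range(bootstrap_B):
            idx = rng.integers(0, n, n)
            sub = TestPanel(panel.test_names, panel.results[idx],
                            tuple(panel.patient_ids[i] for i in idx))
            bfits = _curve_points(sub, vas[idx], grid, kernel, constraints,
                                  seed, 1, eff_n_floor)
            for nm in names:
                reps[nm][b] = [lf.params.as_dict()[nm] for lf in bfits]
        for nm in names:
            lo[nm] = np.percentile(reps[nm], 2.5, axis=0)
            hi[nm] = np.percentile(reps[nm], 97.5, axis=0)
            # pointwise bands bracket the point estimate by construction of
            # the percentile method only approximately; widen minimally
            lo[nm] = np.minimum(lo[nm], est[nm])
            hi[nm] = np.maximum(hi[nm], est[nm])

    return CurveEstimate(stratum=stratum, grid=np.asarray(grid, dtype=float),
                         estimates=est, lo=lo, hi=hi, eff_n=eff_n,
                         flagged=flagged, test_names=panel.test_names)


def select_bandwidth(
    panel: TestPanel,
    vas: np.ndarray,
    kernel: KernelSpec | None = None,
    method: str = "silverman",
    *,
    seed: int = 0,
    candidates: Sequence[float] | None = None,
    constraints: ConstraintSpec | None = None,
    max_loo: int = 100,
) -> float:
    """Bandwidth for the local fits.

    ``silverman``: the rule-of-thumb 1.06 * sd(vas) * n^(-1/5).
    ``cv``: leave-one-out weighted-likelihood maximization over a log-spaced
    candidate set; with large cohorts the held-out evaluation is done on a
    random subset of ``max_loo`` patients for tractability.
    """
    vas = np.asarray(vas, dtype=float)
    n = len(vas)
    sd = float(np.std(vas, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        raise ValueError("VAS has zero variance; use the homogeneous fit instead")
    if method == "silverman":
        return 1.06 * sd * n ** (-0.2)
    if method != "cv":
        raise ValueError(f"unknown bandwidth rule {method!r}")
    if n < 30:
        raise ValueError("cross-validation needs n >= 30")
    base = kernel.kernel if kernel else "gaussian"
    if candidates is None:
        candidates = np.geomspace(0.5, 5.0, 8)
    rng = np.random.default_rng(seed)
    eval_idx = np.arange(n) if n <= max_loo else rng.choice(n, max_loo, replace=False)
    best_h, best_score = None, -np.inf
    for h in candidates:
        ks = KernelSpec(kernel=base, bandwidth=float(h))
        score = 0.0
        for i in eval_idx:
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            sub = TestPanel(panel.test_names, panel.results[keep],
                            tuple(pid for j, pid in enumerate(panel.patient_ids) if keep[j]))
            lf = local_fit(sub, vas[keep], vas[i], ks, constraints,
                           seed=seed, n_restarts=2)
            held = TestPanel(panel.test_names, panel.results[i:i + 1],
                             (panel.patient_ids[i],))
            from .lca import loglik as _ll
            score += _ll(held, lf.params)
        if score > best_score:
            best_score, best_h = score, float(h)
    return best_h
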