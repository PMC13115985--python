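"""Two-class latent class model for K binary diagnostic tests, fit by EM.

This is the Hui–Walter-style model at the heart of the package: true disease
status D is unobserved; each test k has class-conditional operating
characteristics (sensitivity Se_k, specificity Sp_k); tests are assumed
conditionally independent given D.  The observed-data likelihood for patient i
with results y_i (missing entries skipped) is

    L_i = pi * prod_k Se_k^y  (1-Se_k)^(1-y)
        + (1-pi) * prod_k (1-Sp_k)^y  Sp_k^(1-y)

Constraints (ConstraintSpec) pin selected parameters: by convention the
surgical reference (laparoscopy) has its specificity fixed at 1 — surgery
essentially never "finds" endometriosis in a truly disease-free patient —
while its sensitivity is left free, acknowledging the known false-negative
rate of laparoscopy.  Label switching is resolved by requiring the anchor
test's Youden index (Se + Sp - 1) to be non-negative.

EM iterations internally collapse the panel to its distinct response
patterns (at most 3^K with missingness), so a fit costs the same at
n = 2,000 as at n = 50.  Parameters may reach the [0, 1] boundary; no
penalty is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .records import TestPanel

__all__ = [
    "LatentClassParams",
    "ConstraintSpec",
    "FitResult",
    "EmptyClassError",
    "loglik",
    "e_step",
    "m_step",
    "fit_em",
    "naive_accuracy",
]


class EmptyClassError(RuntimeError):
    """A class collapsed to zero total responsibility during an M-step."""


@dataclass(frozen=True)
class LatentClassParams:
    """Prevalence plus per-test sensitivity and specificity."""

    prevalence: float
    se: np.ndarray  # (K,)
    sp: np.ndarray  # (K,)
    test_names: tuple[str, ...]

    def __post_init__(self):
        se = np.asarray(self.se, dtype=float)
        sp = np.asarray(self.sp, dtype=float)
        if se.shape != sp.shape or se.shape != (len(self.test_names),):
            raise ValueError("se/sp must have one entry per test")
        for name, arr in (("prevalence", np.array([self.prevalence])), ("se", se), ("sp", sp)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} outside [0, 1]")
        object.__setattr__(self, "se", se)
        object.__setattr__(self, "sp", sp)

    def as_dict(self) -> dict:
        out = {"prevalence": float(self.prevalence)}
        for k, name in enumerate(self.test_names):
            out[f"se_{name}"] = float(self.se[k])
            out[f"sp_{name}"] = float(self.sp[k])
        return out

    def youden(self, test: str) -> float:
        k = self.test_names.index(test)
        return float(self.se[k] + self.sp[k] - 1.0)


@dataclass(frozen=True)
class ConstraintSpec:
    """Fixed parameters and the label-anchoring rule.

    ``fixed`` maps names of the form ``"se:<test>"`` / ``"sp:<test>"`` /
    ``"prevalence"`` to values in [0, 1].  ``anchor_test`` names the test whose
    Youden index is forced non-negative when resolving label switching.
    ``free_reference_sensitivity`` is a readability flag: the default spec
    fixes laparoscopy specificity at 1 while estimating its sensitivity.
    """

    fixed: Mapping[str, float] = field(default_factory=dict)
    anchor_test: str = "laparoscopy"
    free_reference_sensitivity: bool = True

    def __post_init__(self):
        for key, val in self.fixed.items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"fixed value {key}={val} outside [0, 1]")
            if key != "prevalence" and not (key.startswith("se:") or key.startswith("sp:")):
                raise ValueError(f"unknown constraint key {key!r}")
        object.__setattr__(self, "fixed", dict(self.fixed))

    @classmethod
    def default(cls, reference: str = "laparoscopy") -> "ConstraintSpec":
        """Reference specificity pinned at 1, its sensitivity estimated."""
        return cls(fixed={f"sp:{reference}": 1.0}, anchor_test=reference)

    @classmethod
    def none(cls, anchor_test: str = "laparoscopy") -> "ConstraintSpec":
        return cls(fixed={}, anchor_test=anchor_test)

    def apply(self, params: LatentClassParams) -> LatentClassParams:
        prev, se, sp = params.prevalence, params.se.copy(), params.sp.copy()
        for key, val in self.fixed.items():
            if key == "prevalence":
                prev = val
            else:
                kind, test = key.split(":", 1)
                k = params.test_names.index(test)
                if kind == "se":
                    se[k] = val
                else:
                    sp[k] = val
        return LatentClassParams(prev, se, sp, params.test_names)

    def satisfied_by(self, params: LatentClassParams, atol: float = 1e-12) -> bool:
        d = params.as_dict()
        for key, val in self.fixed.items():
            name = key.replace(":", "_") if key != "prevalence" else key
            if abs(d[name] - val) > atol:
                return False
        return True


@dataclass(frozen=True)
class FitResult:
    """Outcome of an EM fit: parameters, likelihood trace, posteriors."""

    params: LatentClassParams
    loglik: float
    responsibilities: np.ndarray  # gamma_i = P(D=1 | y_i), (n,)
    n_iter: int
    converged: bool
    restarts_used: int
    loglik_trace: np.ndarray
    flags: tuple[str, ...] = ()

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "params": self.params.as_dict(),
            "loglik": float(self.loglik),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "restarts_used": int(self.restarts_used),
            "flags": list(self.flags),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# pattern collapsing — the whole fit runs on distinct response patterns
# ---------------------------------------------------------------------------

def _encode(results: np.ndarray) -> np.ndarray:
    """(n, K) float with NaN -> (n, K) int8 with missing = -1."""
    enc = np.where(np.isnan(results), -1, results).astype(np.int8)
    return enc


def _collapse(enc: np.ndarray, weights: np.ndarray | None):
    """Unique response patterns, their aggregated weights, and the inverse map."""
    patterns, inverse = np.unique(enc, axis=0, return_inverse=True)
    if weights is None:
        wts = np.bincount(inverse, minlength=len(patterns)).astype(float)
    else:
        wts = np.bincount(inverse, weights=weights, minlength=len(patterns))
    return patterns, wts, inverse


def _class_probs(patterns: np.ndarray, params: LatentClassParams):
    """P(pattern | D=1) and P(pattern | D=0) for each distinct pattern."""
    se, sp = params.se, params.sp
    pos = np.ones(len(patterns))
    neg = np.ones(len(patterns))
    for k in range(patterns.shape[1]):
        y = patterns[:, k]
        obs_pos = np.where(y == 1, se[k], np.where(y == 0, 1.0 - se[k], 1.0))
        obs_neg = np.where(y == 1, 1.0 - sp[k], np.where(y == 0, sp[k], 1.0))
        pos *= obs_pos
        neg *= obs_neg
    return pos, neg


def _pattern_posterior(patterns, params):
    """(gamma per pattern, mixture probability per pattern, zero-prob flag)."""
    a, b = _class_probs(patterns, params)
    pi = params.prevalence
    mix = pi * a + (1.0 - pi) * b
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(mix > 0, pi * a / np.where(mix > 0, mix, 1.0), pi)
    return gamma, mix, mix <= 0


# ---------------------------------------------------------------------------
# public likelihood / E / M operations (per-patient contracts)
# ---------------------------------------------------------------------------

def loglik(panel: TestPanel, params: LatentClassParams,
           weights: np.ndarray | None = None) -> float:
    """Observed-data log-likelihood of the two-class mixture.

    Missing results are skipped.  A response pattern with probability zero
    under the (possibly constrained) parameters contributes -inf.
    """
    enc = _encode(panel.results)
    patterns, wts, _ = _collapse(enc, weights)
    _, mix, zero = _pattern_posterior(patterns, params)
    if zero.any() and (wts[zero] > 0).any():
        return float("-inf")
    return float(np.sum(wts * np.log(mix)))


def e_step(panel: TestPanel, params: LatentClassParams) -> np.ndarray:
    """Posterior disease probability gamma_i for every patient.

    Patterns with zero probability under both classes (possible under hard
    constraints) fall back to the prior prevalence.  A patient positive on a
    test whose specificity is 1 gets gamma = 1 exactly: a false positive is
    impossible under that constraint.
    """
    enc = _encode(panel.results)
    patterns, _, inverse = _collapse(enc, None)
    gamma, _, _ = _pattern_posterior(patterns, params)
    return gamma[inverse]


def m_step(panel: TestPanel, gamma: np.ndarray, constraints: ConstraintSpec,
           weights: np.ndarray | None = None) -> LatentClassParams:
    """Weighted-average parameter updates given responsibilities.

    pi    = sum(w * gamma) / sum(w)
    Se_k  = sum(w * gamma * y_k) / sum(w * gamma)           over observed y_k
    Sp_k  = sum(w * (1-gamma) * (1-y_k)) / sum(w * (1-gamma))  over observed
    Fixed parameters are overwritten with their constrained values afterwards.
    """
    gamma = np.asarray(gamma, dtype=float)
    w = np.ones(panel.n) if weights is None else np.asarray(weights, dtype=float)
    wg = w * gamma
    wh = w * (1.0 - gamma)
    tot = w.sum()
    if wg.sum() <= 0 or wh.sum() <= 0:
        raise EmptyClassError("a latent class has zero total responsibility")
    pi = wg.sum() / tot
    K = panel.n_tests
    se = np.empty(K)
    sp = np.empty(K)
    res = panel.results
    for k in range(K):
        obs = ~np.isnan(res[:, k])
        y = res[obs, k]
        g, h = wg[obs], wh[obs]
        if g.sum() <= 0 or h.sum() <= 0:
            raise EmptyClassError(f"no effective observations for test {k} in a class")
        se[k] = float((g * y).sum() / g.sum())
        sp[k] = float((h * (1.0 - y)).sum() / h.sum())
    params = LatentClassParams(pi, se, sp, panel.test_names)
    return constraints.apply(params)


# ---------------------------------------------------------------------------
# full EM fit
# ---------------------------------------------------------------------------

def _compile_constraints(constraints: ConstraintSpec, test_names: Sequence[str]):
    """Constraint spec -> (fixed prevalence or None, se indices/values, sp ...)."""
    prev = None
    se_i, se_v, sp_i, sp_v = [], [], [], []
    for key, val in constraints.fixed.items():
        if key == "prevalence":
            prev = val
        else:
            kind, test = key.split(":", 1)
            k = list(test_names).index(test)
            (se_i if kind == "se" else sp_i).append(k)
            (se_v if kind == "se" else sp_v).append(val)
    return (prev, np.array(se_i, dtype=int), np.array(se_v),
            np.array(sp_i, dtype=int), np.array(sp_v))


try:  # compiled inner loop; the numpy path below is the reference fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _em_core_py(Y1, Y0, wts, pi, se, sp, fx_prev, se_i, se_v, sp_i, sp_v,
                tol, max_iter):
    """EM iterations on collapsed patterns (pure python/numba-compatible).

    Returns (pi, se, sp, trace, n_stored, converged, status); status 0 = ok,
    1 = empty class, 2 = empty class for a test column.
    """
    P, K = Y1.shape
    trace = np.empty(max_iter + 2)
    tot = 0.0
    for p in range(P):
        tot += wts[p]
    gamma = np.empty(P)
    num_se = np.empty(K)
    den_se = np.empty(K)
    num_sp = np.empty(K)
    den_sp = np.empty(K)
    ll_prev = -np.inf
    converged = False
    n_stored = 0
    status = 0
    for _ in range(max_iter):
        ll = 0.0
        neg_inf = False
        for p in range(P):
            ap = 1.0
            bp = 1.0
            for k in range(K):
                if Y1[p, k]:
                    ap *= se[k]
                    bp *= 1.0 - sp[k]
                elif Y0[p, k]:
                    ap *= 1.0 - se[k]
                    bp *= sp[k]
            mix = pi * ap + (1.0 - pi) * bp
            if mix <= 0.0:
                if wts[p] > 0.0:
                    neg_inf = True
                gamma[p] = pi
            else:
                gamma[p] = pi * ap / mix
                ll += wts[p] * np.log(mix)
        if neg_inf:
            ll = -np.inf
        trace[n_stored] = ll
        n_stored += 1
        # M-step
        sg = 0.0
        sh = 0.0
        for k in range(K):
            num_se[k] = 0.0
            den_se[k] = 0.0
            num_sp[k] = 0.0
            den_sp[k] = 0.0
        for p in range(P):
            wgp = wts[p] * gamma[p]
            whp = wts[p] - wgp
            sg += wgp
            sh += whp
            for k in range(K):
                if Y1[p, k]:
                    num_se[k] += wgp
                    den_se[k] += wgp
                    den_sp[k] += whp
                elif Y0[p, k]:
                    den_se[k] += wgp
                    num_sp[k] += whp
                    den_sp[k] += whp
        if sg <= 0.0 or sh <= 0.0:
            status = 1
            break
        bad = False
        for k in range(K):
            if den_se[k] <= 0.0 or den_sp[k] <= 0.0:
                bad = True
        if bad:
            status = 2
            break
        pi = sg / tot
        for k in range(K):
            se[k] = num_se[k] / den_se[k]
            sp[k] = num_sp[k] / den_sp[k]
        if not np.isnan(fx_prev):
            pi = fx_prev
        for j in range(len(se_i)):
            se[se_i[j]] = se_v[j]
        for j in range(len(sp_i)):
            sp[sp_i[j]] = sp_v[j]
        if np.isfinite(ll) and np.isfinite(ll_prev) \
                and abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    # log-likelihood at the returned parameters themselves
    ll = 0.0
    neg_inf = False
    for p in range(P):
        ap = 1.0
        bp = 1.0
        for k in range(K):
            if Y1[p, k]:
                ap *= se[k]
                bp *= 1.0 - sp[k]
            elif Y0[p, k]:
                ap *= 1.0 - se[k]
                bp *= sp[k]
        mix = pi * ap + (1.0 - pi) * bp
        if mix <= 0.0:
            if wts[p] > 0.0:
                neg_inf = True
        else:
            ll += wts[p] * np.log(mix)
    if neg_inf:
        ll = -np.inf
    trace[n_stored] = ll
    n_stored += 1
    return pi, se, sp, trace, n_stored, converged, status


_em_core = _njit(cache=False)(_em_core_py) if _njit is not None else _em_core_py


def _em_run(patterns, wts, test_names, constraints, init: LatentClassParams,
            tol: float, max_iter: int):
    """One EM run on collapsed patterns; returns (params, loglik, trace, conv).

    Operates on raw arrays — the parameter dataclass is only built at the end.
    """
    Y1 = patterns == 1
    Y0 = patterns == 0
    fx_prev, se_i, se_v, sp_i, sp_v = _compile_constraints(constraints, test_names)

    pi0 = float(init.prevalence) if fx_prev is None else fx_prev
    se0 = init.se.copy()
    sp0 = init.sp.copy()
    se0[se_i] = se_v
    sp0[sp_i] = sp_v
    pi, se, sp, trace, n_stored, converged, status = _em_core(
        Y1, Y0, np.asarray(wts, dtype=float), pi0, se0, sp0,
        np.nan if fx_prev is None else float(fx_prev),
        se_i, se_v, sp_i, sp_v, tol, max_iter)
    if status == 1:
        raise EmptyClassError("empty class during EM")
    if status == 2:
        raise EmptyClassError("no effective observations for a test in a class")
    params = LatentClassParams(pi, se, sp, tuple(test_names))
    ll = float(trace[n_stored - 1])
    return params, ll, trace[:n_stored].copy(), converged


def _em_run_reference(patterns, wts, test_names, constraints,
                      init: LatentClassParams, tol: float, max_iter: int):
    """Vectorized-numpy EM run; kept as an in-package cross-check of the
    compiled loop (same updates expressed independently)."""
    Y1 = patterns == 1
    Y0 = patterns == 0
    obs = Y1 | Y0
    fx_prev, se_i, se_v, sp_i, sp_v = _compile_constraints(constraints, test_names)

    def clamp(pi, se, sp):
        if fx_prev is not None:
            pi = fx_prev
        se = se.copy()
        sp = sp.copy()
        se[se_i] = se_v
        sp[sp_i] = sp_v
        return pi, se, sp

    pi, se, sp = clamp(float(init.prevalence), init.se, init.sp)
    trace: list[float] = []
    ll_prev = -np.inf
    tot = wts.sum()
    pos = wts > 0
    converged = False
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            a = np.prod(np.where(Y1, se, np.where(Y0, 1.0 - se, 1.0)), axis=1)
            b = np.prod(np.where(Y1, 1.0 - sp, np.where(Y0, sp, 1.0)), axis=1)
            mix = pi * a + (1.0 - pi) * b
            zero = mix <= 0
            ll = float("-inf") if (zero & pos).any() \
                else float(wts @ np.log(mix))
            trace.append(ll)
            gamma = np.where(zero, pi, pi * a / np.where(zero, 1.0, mix))
            wg = wts * gamma
            wh = wts - wg
            sg, sh = wg.sum(), wh.sum()
            if sg <= 0 or sh <= 0:
                raise EmptyClassError("empty class during EM")
            den_se = wg @ obs
            den_sp = wh @ obs
            if (den_se <= 0).any() or (den_sp <= 0).any():
                raise EmptyClassError("no effective observations for a test in a class")
            se = (wg @ Y1) / den_se
            sp = (wh @ Y0) / den_sp
            pi, se, sp = clamp(sg / tot, se, sp)
            if np.isfinite(ll) and np.isfinite(ll_prev) \
                    and abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_prev = ll
        # log-likelihood at the returned parameters themselves
        a = np.prod(np.where(Y1, se, np.where(Y0, 1.0 - se, 1.0)), axis=1)
        b = np.prod(np.where(Y1, 1.0 - sp, np.where(Y0, sp, 1.0)), axis=1)
        mix = pi * a + (1.0 - pi) * b
        ll = float("-inf") if ((mix <= 0) & pos).any() else float(wts @ np.log(mix))
    trace.append(ll)
    params = LatentClassParams(pi, se, sp, tuple(test_names))
    return params, ll, np.array(trace), converged


def _resolve_labels(params: LatentClassParams, constraints: ConstraintSpec):
    """Swap class labels if the anchor test is anti-informative.

    The mirrored parameterization (pi -> 1-pi, Se <-> 1-Sp) has the same
    likelihood; we keep the branch where the anchor's Youden index is >= 0,
    unless the swap would break a hard constraint.
    """
    if params.youden(constraints.anchor_test) >= 0:
        return params, False
    swapped = LatentClassParams(
        1.0 - params.prevalence, 1.0 - params.sp, 1.0 - params.se, params.test_names
    )
    if constraints.satisfied_by(swapped):
        return swapped, True
    return params, False


def fit_em(
    panel: TestPanel,
    constraints: ConstraintSpec | None = None,
    *,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int,
    weights: np.ndarray | None = None,
    init: LatentClassParams | None = None,
) -> FitResult:
    """Best-of-restarts constrained EM fit.

    One informed initialization (cross-tabulation against the anchor test via
    :func:`naive_accuracy`, when its column is complete) plus uniform-random
    restarts.  Deterministic under a fixed ``seed``.  When ``init`` is given
    it replaces the informed start (used for warm-started bootstrap refits).

    With fewer than three tests and no fixed constraints the single-population
    model is not identifiable; the fit proceeds but is flagged.
    """
    if constraints is None:
        constraints = ConstraintSpec.default(panel.test_names[0])
    flags: list[str] = []
    if panel.n_tests < 3 and not constraints.fixed:
        flags.append("non_identifiable: fewer than 3 tests and no constraints")
        warnings.warn(flags[-1], stacklevel=2)

    enc = _encode(panel.results)
    patterns, wts, inverse = _collapse(enc, weights)
    rng = np.random.default_rng(seed)
    names = panel.test_names

    inits: list[LatentClassParams] = []
    if init is not None:
        inits.append(init)
    else:
        inits.append(_informed_init(panel, constraints))
    for _ in range(max(0, n_restarts - 1)):
        pi = rng.uniform(0.1, 0.9)
        se = rng.uniform(0.55, 0.95, panel.n_tests)
        sp = rng.uniform(0.55, 0.95, panel.n_tests)
        inits.append(LatentClassParams(pi, se, sp, names))

    best = None
    used = 0
    for start in inits:
        used += 1
        try:
            params, ll, trace, conv = _em_run(
                patterns, wts, names, constraints, start, tol, max_iter
            )
        except EmptyClassError:
            continue
        if best is None or ll > best[1]:
            best = (params, ll, trace, conv)
    if best is None:
        raise EmptyClassError("every EM restart collapsed a class")

    params, ll, trace, conv = best
    params, swapped = _resolve_labels(params, constraints)
    if swapped:
        flags.append("labels_swapped_by_anchor")
    gamma_pat, _, _ = _pattern_posterior(patterns, params)
    return FitResult(
        params=params,
        loglik=ll,
        responsibilities=gamma_pat[inverse],
        n_iter=len(trace),
        converged=conv,
        restarts_used=used,
        loglik_trace=trace,
        flags=tuple(flags),
    )


def _informed_init(panel: TestPanel, constraints: ConstraintSpec) -> LatentClassParams:
    """EM start from cross-tabulation against the anchor test, if usable."""
    names = panel.test_names
    anchor = constraints.anchor_test if constraints.anchor_test in names else names[0]
    ref = panel.column(anchor)
    if np.isnan(ref).any() or len(set(ref)) < 2:
        return LatentClassParams(0.5, np.full(panel.n_tests, 0.8),
                                 np.full(panel.n_tests, 0.8), names)
    acc = naive_accuracy(panel, anchor)
    se = np.array([acc[n][0] for n in names])
    sp = np.array([acc[n][1] for n in names])
    # keep the start interior so EM can move in any direction
    se = np.clip(np.where(np.isnan(se), 0.8, se), 0.05, 0.95)
    sp = np.clip(np.where(np.isnan(sp), 0.8, sp), 0.05, 0.95)
    pi = float(np.clip(np.nanmean(ref), 0.05, 0.95))
    return LatentClassParams(pi, se, sp, names)


def naive_accuracy(panel: TestPanel, reference: str) -> dict[str, tuple[float, float]]:
    """Each test's (Se, Sp) treating ``reference`` as a perfect truth.

    Used as an EM initializer and as the closed-form check that constrained
    EM collapses to when a perfect reference is present.  Undefined cells
    (reference all-positive or all-negative among the pairwise-complete rows)
    come back as NaN.
    """
    ref = panel.column(reference)
    if np.isnan(ref).any():
        raise ValueError("reference column must be complete")
    out: dict[str, tuple[float, float]] = {}
    for name in panel.test_names:
        y = panel.column(name)
        obs = ~np.isnan(y)
        pos = obs & (ref == 1)
        neg = obs & (ref == 0)
        se = float(y[pos].mean()) if pos.any() else float("nan")
        sp = float(1.0 - y[neg].mean()) if neg.any() else float("nan")
        out[name] = (se, sp)
    return out
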