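"""Synthetic patient cohorts with the structure the latent-class analysis assumes.

The generator realizes the two-class model directly: each patient gets a
menstrual-cycle phase, a VAS dysmenorrhea score, and a latent disease status
drawn from a (possibly covariate-varying) prevalence; the three binary tests
(laparoscopy, CEC detection, CA125) are then drawn conditionally independently
given status with the configured class-specific operating characteristics,
which may themselves vary with VAS and phase.

CEC counts follow a hurdle model: the binary detection layer is authoritative
(it carries the configured sensitivity/specificity exactly), and positive
records receive a zero-truncated Poisson count whose mean differs between
true-positive and false-positive detections.  Preoperative medical treatment
multiplies the odds of CEC detection by a configurable factor.  Detected cells
split into small (< 5 um) and large (>= 5 um) subtypes by a per-group binomial
mixture.

Scenario presets package the point estimates of the study's stratified
accuracy tables as generating truths, so parameter-recovery tests and the
acceptance runs simulate from exactly the conditions those tables describe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    Cohort,
    GroupLabel,
    PatientRecord,
    Phase,
    config_digest,
)

__all__ = ["CohortConfig", "GeneratingTruth", "simulate_cohort",
           "scenario_preset", "simulate_subtypes", "PRESET_NAMES"]

ParamFn = float | Callable[[np.ndarray, np.ndarray], np.ndarray]
# a test's operating characteristics: (sensitivity, specificity), each either
# a constant or a function of (vas array, phase code array)

#: small-cell (< 5 um) fraction of detected CECs by clinical group
DEFAULT_SUBTYPE_MIX = {
    "EM_untreated": 0.7406,
    "EM_treated": 0.1250,
    "control": 0.0495,
}


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification for one synthetic cohort.

    Prevalence and per-test (Se, Sp) may be constants or callables of
    (vas, phase_code) returning per-patient probabilities; phase codes are
    0 = menstrual, 1 = proliferative, 2 = secretory.
    """

    n: int
    prevalence: ParamFn
    test_params: Mapping[str, tuple[ParamFn, ParamFn]]
    phase_probs: tuple[float, float, float] = (0.07, 0.40, 0.53)
    # VAS: point mass at 0, remainder a Beta discretized onto 1..10
    vas_zero_prob: float = 0.47
    vas_beta: tuple[float, float] = (1.0, 1.8)
    vas_range: tuple[float, float] | None = None  # restrict to a stratum
    vas_continuous: bool = False
    count_mean_pos: float = 3.0  # zero-truncated Poisson rate, true positives
    count_mean_neg: float = 1.5  # and false positives
    subtype_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX))
    treated_frac: float = 0.0  # P(treated | diseased)
    treatment_effect: float = 0.156  # odds multiplier on CEC detection
    worsened_prob: tuple[float, float] = (0.10, 0.30)  # (healthy, diseased)
    worsened_fixed: bool | None = None  # force the flag (activity strata)
    clinical_frac: float = 0.0  # diseased without surgery (no lap result)
    malignant_frac: float = 0.096  # among controls
    adenomyosis_frac: float = 0.18  # among diseased
    ca125_threshold: float = 35.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        pp = np.asarray(self.phase_probs, dtype=float)
        if pp.shape != (3,) or (pp < 0).any() or abs(pp.sum() - 1.0) > 1e-9:
            raise ValueError("phase_probs must be a 3-simplex")
        for name, val in [("vas_zero_prob", self.vas_zero_prob),
                          ("treated_frac", self.treated_frac),
                          ("clinical_frac", self.clinical_frac),
                          ("malignant_frac", self.malignant_frac),
                          ("adenomyosis_frac", self.adenomyosis_frac)]:
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for test, (se, sp) in self.test_params.items():
            for v in (se, sp):
                if isinstance(v, (int, float)) and not (0.0 <= v <= 1.0):
                    raise ValueError(f"{test} parameter {v} outside [0, 1]")
        if isinstance(self.prevalence, (int, float)) and not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence outside [0, 1]")
        object.__setattr__(self, "test_params", dict(self.test_params))
        object.__setattr__(self, "subtype_mix", dict(self.subtype_mix))

    def to_dict(self) -> dict:
        def enc(v):
            return v if isinstance(v, (int, float, str, bool, type(None))) else repr(v)
        out = {}
        for f in self.__dataclass_fields__:
            v = getattr(self, f)
            if f == "test_params":
                v = {k: [enc(a), enc(b)] for k, (a, b) in v.items()}
            elif isinstance(v, Mapping):
                v = {k: enc(x) for k, x in v.items()}
            elif isinstance(v, tuple):
                v = [enc(x) for x in v]
            else:
                v = enc(v)
            out[f] = v
        return out

    def digest(self) -> str:
        return config_digest(self.to_dict())


@dataclass(frozen=True)
class GeneratingTruth:
    """The realized latent states and the exact generative settings used."""

    config: CohortConfig
    seed: int
    true_status: np.ndarray
    prevalence_used: np.ndarray  # per patient
    se_used: dict[str, np.ndarray]
    sp_used: dict[str, np.ndarray]


def _eval_fn(fn: ParamFn, vas: np.ndarray, phase_code: np.ndarray) -> np.ndarray:
    if callable(fn):
        out = np.asarray(fn(vas, phase_code), dtype=float)
        out = np.broadcast_to(out, vas.shape).copy()
    else:
        out = np.full(vas.shape, float(fn))
    if ((out < 0) | (out > 1)).any():
        raise ValueError("parameter function left [0, 1]")
    return out


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by resampling the zeros."""
    out = rng.poisson(lam, size)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(lam, bad.sum())
        bad = out == 0
    return out


def simulate_cohort(config: CohortConfig, seed: int | None = None
                    ) -> tuple[Cohort, GeneratingTruth]:
    """Draw one cohort from the configured generative model.

    Bit-reproducible: all random substreams are spawned deterministically
    from the single integer seed (``config.seed`` unless overridden).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    r_phase, r_vas, r_status, r_tests, r_counts, r_misc = (
        np.random.default_rng(s) for s in ss.spawn(6))
    n = config.n

    phase_code = r_phase.choice(3, size=n, p=np.asarray(config.phase_probs))
    vas = _draw_vas(r_vas, config, n)
    prev = _eval_fn(config.prevalence, vas, phase_code)
    status = (r_status.uniform(size=n) < prev).astype(int)

    treated = np.zeros(n, dtype=bool)
    if config.treated_frac > 0:
        treated = (r_misc.uniform(size=n) < config.treated_frac) & (status == 1)

    if config.worsened_fixed is not None:
        worsened = np.full(n, bool(config.worsened_fixed))
    else:
        p_w = np.where(status == 1, config.worsened_prob[1], config.worsened_prob[0])
        worsened = r_misc.uniform(size=n) < p_w

    results: dict[str, np.ndarray] = {}
    se_used: dict[str, np.ndarray] = {}
    sp_used: dict[str, np.ndarray] = {}
    for test, (se_fn, sp_fn) in config.test_params.items():
        se = _eval_fn(se_fn, vas, phase_code)
        sp = _eval_fn(sp_fn, vas, phase_code)
        p_pos = np.where(status == 1, se, 1.0 - sp)
        if test == "CEC" and treated.any():
            odds = p_pos / np.clip(1.0 - p_pos, 1e-12, None) * config.treatment_effect
            p_pos = np.where(treated, odds / (1.0 + odds), p_pos)
        results[test] = (r_tests.uniform(size=n) < p_pos).astype(int)
        se_used[test], sp_used[test] = se, sp

    cec_pos = results.get("CEC", np.zeros(n, dtype=int))
    cec_count = np.zeros(n, dtype=int)
    tp = (cec_pos == 1) & (status == 1)
    fp = (cec_pos == 1) & (status == 0)
    if tp.any():
        cec_count[tp] = _zt_poisson(r_counts, config.count_mean_pos, tp.sum())
    if fp.any():
        cec_count[fp] = _zt_poisson(r_counts, config.count_mean_neg, fp.sum())

    ca125_pos = results.get("CA125", np.zeros(n, dtype=int))
    thr = config.ca125_threshold
    ca125_value = np.where(
        ca125_pos == 1,
        thr * (1.0 + r_counts.exponential(0.8, n)),
        np.round(r_counts.uniform(2.0, thr * 0.999, n), 2),
    )
    ca125_value = np.round(ca125_value, 2)
    ca125_value = np.maximum(ca125_value, np.where(ca125_pos == 1, thr, 0.0))

    clinical = (r_misc.uniform(size=n) < config.clinical_frac) & (status == 1)
    malignant = (r_misc.uniform(size=n) < config.malignant_frac) & (status == 0)
    adeno = (r_misc.uniform(size=n) < config.adenomyosis_frac) & (status == 1)

    lap = results.get("laparoscopy")
    digest = config.digest()
    width = len(str(n))
    records = []
    for i in range(n):
        if status[i] == 1:
            group = GroupLabel.EM_CLINICAL if clinical[i] else GroupLabel.EM_SURGICAL
        else:
            group = GroupLabel.CONTROL_MALIGNANT if malignant[i] else GroupLabel.CONTROL_BENIGN
        records.append(PatientRecord(
            patient_id=f"S{i + 1:0{width}d}",
            lap_result=None if clinical[i] or lap is None else int(lap[i]),
            cec_count=int(cec_count[i]),
            ca125_value=float(ca125_value[i]),
            ca125_positive=int(ca125_pos[i]),
            vas=float(vas[i]),
            phase=(Phase.MENSTRUAL, Phase.PROLIFERATIVE, Phase.SECRETORY)[phase_code[i]],
            worsened_6mo=bool(worsened[i]),
            treated=bool(treated[i]),
            group_label=group,
            adenomyosis=bool(adeno[i]),
            true_status=int(status[i]),
        ))
    cohort = Cohort(records=tuple(records), provenance="synthetic", config_hash=digest)
    truth = GeneratingTruth(config=config, seed=seed, true_status=status,
                            prevalence_used=prev, se_used=se_used, sp_used=sp_used)
    return cohort, truth


def _draw_vas(rng: np.random.Generator, config: CohortConfig, n: int) -> np.ndarray:
    """VAS scores: integer grid by default, optionally continuous or range-bound."""
    a, b = config.vas_beta
    if config.vas_range is not None:
        lo, hi = config.vas_range
        if config.vas_continuous:
            return rng.uniform(lo, hi, n)
        return rng.integers(int(lo), int(hi) + 1, n).astype(float)
    if config.vas_continuous:
        zero = rng.uniform(size=n) < config.vas_zero_prob
        v = rng.beta(a, b, n) * 10.0
        return np.where(zero, 0.0, np.maximum(v, 1e-6))
    zero = rng.uniform(size=n) < config.vas_zero_prob
    grid = np.minimum(np.floor(rng.beta(a, b, n) * 10.0).astype(int) + 1, 10)
    return np.where(zero, 0, grid).astype(float)


# ---------------------------------------------------------------------------
# scenario presets — generating truths equal to the study's point estimates
# ---------------------------------------------------------------------------

PRESET_NAMES = ("overall", "by_vas", "active_vs_dormant", "by_phase", "treated")

# (lap Se, lap Sp), (CEC Se, CEC Sp), (CA125 Se, CA125 Sp), prevalence, n
_PRESETS: dict[tuple[str, str | None], dict] = {
    ("overall", None): dict(
        lap=(0.88, 1.00), cec=(0.58, 0.81), ca125=(0.37, 0.754),
        prevalence=0.48, n=279),
    ("by_vas", "none"): dict(
        lap=(0.795, 1.000), cec=(0.655, 0.795), ca125=(0.393, 0.829),
        prevalence=0.48, n=107, vas_range=(0, 0)),
    ("by_vas", "mild"): dict(
        lap=(0.819, 1.000), cec=(0.545, 0.813), ca125=(0.353, 0.810),
        prevalence=0.48, n=62, vas_range=(1, 3)),
    ("by_vas", "moderate"): dict(
        lap=(0.956, 1.000), cec=(0.508, 0.799), ca125=(0.383, 0.472),
        prevalence=0.48, n=31, vas_range=(4, 6)),
    ("by_vas", "severe"): dict(
        lap=(0.759, 1.000), cec=(0.694, 0.946), ca125=(0.355, 0.429),
        prevalence=0.48, n=29, vas_range=(7, 10)),
    ("active_vs_dormant", "active"): dict(
        lap=(0.791, 1.000), cec=(0.734, 0.961), ca125=(0.352, 0.311),
        prevalence=18 / 35, n=35, vas_range=(6, 10), worsened_fixed=True),
    ("active_vs_dormant", "dormant"): dict(
        lap=(0.86, 1.00), cec=(0.54, 0.82), ca125=(0.37, 0.80),
        prevalence=67 / 194, n=194, worsened_fixed=False),
    ("by_phase", "prolif_menstrual"): dict(
        lap=(0.99, 1.00), cec=(0.84, 0.83), ca125=(0.44, 0.65),
        prevalence=0.48, n=98, phase_probs=(0.15, 0.85, 0.0)),
    ("by_phase", "secretory"): dict(
        lap=(0.91, 1.00), cec=(0.52, 0.82), ca125=(0.36, 0.87),
        prevalence=0.48, n=110, phase_probs=(0.0, 0.0, 1.0)),
    ("treated", None): dict(
        lap=(0.88, 1.00), cec=(0.58, 0.81), ca125=(0.37, 0.754),
        prevalence=0.48, n=279, treated_frac=0.211),
}

_DEFAULT_STRATUM = {"by_vas": "severe", "active_vs_dormant": "active",
                    "by_phase": "prolif_menstrual"}


def scenario_preset(name: str, stratum: str | None = None, *,
                    n: int | None = None, seed: int = 0) -> CohortConfig:
    """A documented CohortConfig whose generating parameters equal the
    corresponding stratified-table point estimates.

    ``stratum`` selects the row within a stratified scenario (``by_vas``:
    none/mild/moderate/severe; ``active_vs_dormant``: active/dormant;
    ``by_phase``: prolif_menstrual/secretory).  ``n`` overrides the study's
    stratum size (recovery simulations use larger cohorts).
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown scenario {name!r}; choose from {PRESET_NAMES}")
    if stratum is None:
        stratum = _DEFAULT_STRATUM.get(name)
    key = (name, stratum)
    if key not in _PRESETS:
        valid = sorted(s for nm, s in _PRESETS if nm == name)
        raise KeyError(f"unknown stratum {stratum!r} for scenario {name!r}; "
                       f"choose from {valid}")
    p = dict(_PRESETS[key])
    cfg = CohortConfig(
        n=n if n is not None else p["n"],
        prevalence=p["prevalence"],
        test_params={
            "laparoscopy": p["lap"],
            "CEC": p["cec"],
            "CA125": p["ca125"],
        },
        phase_probs=p.get("phase_probs", (0.07, 0.40, 0.53)),
        vas_range=p.get("vas_range"),
        treated_frac=p.get("treated_frac", 0.0),
        worsened_fixed=p.get("worsened_fixed"),
        seed=seed,
    )
    return cfg


def simulate_subtypes(cohort: Cohort, config: CohortConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Split each patient's CEC count into small (< 5 um) and large cells.

    The small-cell fraction depends on clinical group: untreated endometriosis
    patients carry mostly small cells, controls and treated patients mostly
    large ones.  Returns a frame with columns patient_id, group, small, large.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(7)[6])
    mix = config.subtype_mix
    rows = []
    for r in cohort:
        if r.group_label in (GroupLabel.EM_SURGICAL, GroupLabel.EM_CLINICAL):
            key = "EM_treated" if r.treated else "EM_untreated"
        else:
            key = "control"
        p_small = mix[key]
        small = int(rng.binomial(r.cec_count, p_small)) if r.cec_count else 0
        rows.append({"patient_id": r.patient_id, "group": key,
                     "small": small, "large": r.cec_count - small})
    return pd.DataFrame(rows, columns=["patient_id", "group", "small", "large"])
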