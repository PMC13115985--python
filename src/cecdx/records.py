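"""Patient records, cohort I/O, and deterministic clinical classification rules.

The study design this package models evaluates three diagnostic tests for
endometriosis — laparoscopy, circulating endometrial cell (CEC) detection in
peripheral blood, and serum CA125 — on a cohort of women with pelvic masses.
None of the three is a gold standard, so records carry all three results plus
the covariates (VAS dysmenorrhea score, menstrual-cycle phase, symptom
worsening, treatment status) that the latent-class analysis conditions on.

This module owns the plain-CSV representation of a cohort and the handful of
deterministic rules the study applies before any model fitting:

* CEC positivity: at least one circulating endometrial cell per 6 mL of blood.
* CA125 positivity: value at or above a clinical threshold (35 U/mL default).
* Dysmenorrhea severity strata on the 0–10 VAS: 0 / 1–3 / 4–6 / 7–10.
* Lesion activity: dysmenorrhea markedly worsened over six months AND
  moderate-to-severe pain (VAS >= 6).
* Cycle-phase pooling: menstrual pooled with proliferative (small menstrual
  subgroup), secretory kept separate.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "PooledPhase",
    "VasStratum",
    "Activity",
    "GroupLabel",
    "PatientRecord",
    "Cohort",
    "TestPanel",
    "DEFAULT_CA125_THRESHOLD",
    "DEFAULT_TEST_NAMES",
    "CohortValidationError",
    "binarize_cec",
    "binarize_ca125",
    "vas_stratum",
    "classify_activity",
    "pool_phase",
    "read_cohort",
    "write_cohort",
    "build_test_panel",
]

DEFAULT_CA125_THRESHOLD = 35.0  # U/mL, conventional clinical cut-off
DEFAULT_TEST_NAMES = ("laparoscopy", "CEC", "CA125")


class Phase(str, Enum):
    MENSTRUAL = "menstrual"
    PROLIFERATIVE = "proliferative"
    SECRETORY = "secretory"


class PooledPhase(str, Enum):
    PROLIF_MENSTRUAL = "prolif_menstrual"
    SECRETORY = "secretory"


class VasStratum(str, Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class Activity(str, Enum):
    ACTIVE = "active"
    DORMANT = "dormant"


class GroupLabel(str, Enum):
    EM_SURGICAL = "EM_surgical"
    EM_CLINICAL = "EM_clinical"
    CONTROL_BENIGN = "control_benign"
    CONTROL_MALIGNANT = "control_malignant"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the record invariants.

    ``row_errors`` maps 0-based data-row indices to human-readable messages.
    """

    def __init__(self, message: str, row_errors: Mapping[int, str] | None = None):
        super().__init__(message)
        self.row_errors: dict[int, str] = dict(row_errors or {})


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def binarize_cec(cec_count: int) -> int:
    """CEC positivity: at least one circulating endometrial cell per 6 mL."""
    if cec_count < 0:
        raise ValueError(f"cec_count must be >= 0, got {cec_count}")
    return int(cec_count >= 1)


def binarize_ca125(value: float, threshold: float = DEFAULT_CA125_THRESHOLD) -> int:
    """CA125 positivity at a clinical threshold (inclusive); default 35 U/mL."""
    if value < 0:
        raise ValueError(f"CA125 value must be >= 0, got {value}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return int(value >= threshold)


def _check_vas(vas: float) -> float:
    if not (0.0 <= vas <= 10.0) or math.isnan(vas):
        raise ValueError(f"VAS must lie in [0, 10], got {vas}")
    return float(vas)


def vas_stratum(vas: float) -> VasStratum:
    """Dysmenorrhea severity stratum from the VAS pain score.

    Integer bands: 0 = none, 1–3 = mild, 4–6 = moderate, 7–10 = severe.
    Fractional scores are rounded half-up to the nearest integer first, so
    the strata partition the whole interval [0, 10].
    """
    v = _check_vas(vas)
    vi = int(math.floor(v + 0.5))  # round half-up; VAS is non-negative
    if vi == 0:
        return VasStratum.NONE
    if vi <= 3:
        return VasStratum.MILD
    if vi <= 6:
        return VasStratum.MODERATE
    return VasStratum.SEVERE


def classify_activity(worsened_6mo: bool, vas: float, *, min_vas: float = 6.0) -> Activity:
    """Lesion activity: marked symptom worsening plus moderate-to-severe pain.

    ``active`` requires BOTH a significant worsening of dysmenorrhea over the
    past six months and a VAS of at least ``min_vas`` (default 6).  The
    threshold is exposed because "moderate-to-severe" could also be read as
    stratum membership (VAS >= 4); the strict VAS >= 6 reading is the default.
    """
    v = _check_vas(vas)
    return Activity.ACTIVE if (bool(worsened_6mo) and v >= min_vas) else Activity.DORMANT


def pool_phase(phase: Phase | str) -> PooledPhase:
    """Pool the menstrual with the proliferative phase; keep secretory apart."""
    p = Phase(phase)
    if p in (Phase.MENSTRUAL, Phase.PROLIFERATIVE):
        return PooledPhase.PROLIF_MENSTRUAL
    return PooledPhase.SECRETORY


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One study participant.

    ``lap_result`` and the CA125 fields may be missing (None): clinically
    diagnosed patients without surgery and patients without a CA125 draw are
    retained and handled pairwise downstream.  ``true_status`` exists only in
    synthetic cohorts, where the generating latent disease state is known.
    """

    patient_id: str
    lap_result: int | None
    cec_count: int
    ca125_value: float | None
    ca125_positive: int | None
    vas: float
    phase: Phase
    worsened_6mo: bool
    treated: bool
    group_label: GroupLabel
    adenomyosis: bool = False
    true_status: int | None = None

    def validate(self, ca125_threshold: float = DEFAULT_CA125_THRESHOLD) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        if self.cec_count < 0 or int(self.cec_count) != self.cec_count:
            raise ValueError(f"cec_count must be a non-negative integer, got {self.cec_count}")
        _check_vas(self.vas)
        for name in ("lap_result", "ca125_positive", "true_status"):
            val = getattr(self, name)
            if val is not None and val not in (0, 1):
                raise ValueError(f"{name} must be 0, 1 or missing, got {val}")
        if self.ca125_value is not None:
            if self.ca125_value < 0:
                raise ValueError(f"ca125_value must be >= 0, got {self.ca125_value}")
            if self.ca125_positive is not None:
                implied = binarize_ca125(self.ca125_value, ca125_threshold)
                if implied != self.ca125_positive:
                    raise ValueError(
                        f"ca125_positive={self.ca125_positive} inconsistent with "
                        f"value {self.ca125_value} at threshold {ca125_threshold}"
                    )

    @property
    def cec_positive(self) -> int:
        return binarize_cec(self.cec_count)

    @property
    def stratum(self) -> VasStratum:
        return vas_stratum(self.vas)

    @property
    def activity(self) -> Activity:
        return classify_activity(self.worsened_6mo, self.vas)

    @property
    def pooled_phase(self) -> PooledPhase:
        return pool_phase(self.phase)


_CSV_COLUMNS = [f.name for f in fields(PatientRecord)]


@dataclass(frozen=True)
class Cohort:
    """An ordered, validated collection of patient records."""

    records: tuple[PatientRecord, ...]
    provenance: str = "observed"  # "observed" | "synthetic"
    config_hash: str | None = None

    def __post_init__(self):
        if len(self.records) == 0:
            raise ValueError("cohort must be nonempty")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id(s): {dupes[:5]}")
        if self.provenance not in ("observed", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep: Iterable[bool] | Iterable[int]) -> "Cohort":
        keep = list(keep)
        if keep and isinstance(keep[0], (bool, np.bool_)):
            recs = tuple(r for r, k in zip(self.records, keep) if k)
        else:
            recs = tuple(self.records[i] for i in keep)
        return Cohort(records=recs, provenance=self.provenance, config_hash=self.config_hash)

    def resample(self, indices: Iterable[int]) -> "Cohort":
        """Bootstrap resample: repeated draws get a '#k' id suffix so the
        unique-patient_id invariant still holds."""
        seen: dict[str, int] = {}
        recs = []
        for i in indices:
            r = self.records[i]
            k = seen.get(r.patient_id, 0)
            seen[r.patient_id] = k + 1
            recs.append(r if k == 0 else replace(r, patient_id=f"{r.patient_id}#{k}"))
        return Cohort(records=tuple(recs), provenance=self.provenance,
                      config_hash=self.config_hash)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "patient_id": r.patient_id,
                "lap_result": r.lap_result,
                "cec_count": r.cec_count,
                "ca125_value": r.ca125_value,
                "ca125_positive": r.ca125_positive,
                "vas": r.vas,
                "phase": r.phase.value,
                "worsened_6mo": int(r.worsened_6mo),
                "treated": int(r.treated),
                "group_label": r.group_label.value,
                "adenomyosis": int(r.adenomyosis),
                "true_status": r.true_status,
            })
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    @property
    def vas_values(self) -> np.ndarray:
        return np.array([r.vas for r in self.records], dtype=float)


@dataclass(frozen=True)
class TestPanel:
    """Per-patient binary results for an ordered set of tests.

    ``results`` is an (n, K) float array holding 0.0, 1.0 or NaN (missing);
    ``mask`` is True where a result is observed.
    """

    test_names: tuple[str, ...]
    results: np.ndarray
    patient_ids: tuple[str, ...]

    def __post_init__(self):
        res = np.asarray(self.results, dtype=float)
        if res.ndim != 2 or res.shape[1] != len(self.test_names):
            raise ValueError("results must be (n, K) with K = len(test_names)")
        observed = res[~np.isnan(res)]
        if not np.isin(observed, (0.0, 1.0)).all():
            raise ValueError("results must be binary or missing")
        object.__setattr__(self, "results", res)

    @property
    def n(self) -> int:
        return self.results.shape[0]

    @property
    def n_tests(self) -> int:
        return self.results.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.results)

    def column(self, test: str) -> np.ndarray:
        return self.results[:, self.test_names.index(test)]


def build_test_panel(
    cohort: Cohort,
    test_names: Sequence[str] = DEFAULT_TEST_NAMES,
    ca125_threshold: float = DEFAULT_CA125_THRESHOLD,
) -> TestPanel:
    """Assemble the binary test matrix (laparoscopy, CEC, CA125) from a cohort.

    CEC is binarized at >= 1 cell / 6 mL.  CA125 uses the recorded binary flag
    when present, otherwise the value dichotomized at ``ca125_threshold``.
    Missing results stay missing (NaN).
    """
    cols = {}
    n = len(cohort)
    for name in test_names:
        col = np.full(n, np.nan)
        for i, r in enumerate(cohort):
            if name == "laparoscopy":
                if r.lap_result is not None:
                    col[i] = r.lap_result
            elif name == "CEC":
                col[i] = binarize_cec(r.cec_count)
            elif name == "CA125":
                if r.ca125_positive is not None:
                    col[i] = r.ca125_positive
                elif r.ca125_value is not None:
                    col[i] = binarize_ca125(r.ca125_value, ca125_threshold)
            else:
                raise KeyError(f"unknown test {name!r}")
        cols[name] = col
    results = np.column_stack([cols[name] for name in test_names])
    return TestPanel(
        test_names=tuple(test_names),
        results=results,
        patient_ids=tuple(r.patient_id for r in cohort),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_OPTIONAL_INT = ("lap_result", "ca125_positive", "true_status")
_MANDATORY = ("patient_id", "cec_count", "vas", "phase", "worsened_6mo",
              "treated", "group_label")


def _parse_optional_binary(raw, name: str) -> int | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    v = float(raw)
    if v not in (0.0, 1.0):
        raise ValueError(f"{name} must be 0/1/empty, got {raw!r}")
    return int(v)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    provenance: str = "observed",
    ca125_threshold: float = DEFAULT_CA125_THRESHOLD,
) -> Cohort:
    """Read and validate a cohort from a plain CSV file.

    Parameters
    ----------
    path
        UTF-8 comma-separated file with a header row, one row per patient.
    schema
        Optional mapping from canonical column names (``patient_id``,
        ``cec_count``, ...) to the names used in the file; identity by default.
        May also be a path to a JSON file holding that mapping.

    Raises
    ------
    CohortValidationError
        If mandatory columns are missing, or any row violates an invariant.
        Row-level problems are collected and reported together with their
        0-based data-row indices.
    """
    if isinstance(schema, (str, Path)):
        schema = json.loads(Path(schema).read_text())
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype={schema.get("patient_id", "patient_id"): str})
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)

    missing_cols = [c for c in _MANDATORY if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing mandatory column(s): {missing_cols}")

    records: list[PatientRecord] = []
    row_errors: dict[int, str] = {}
    for i, row in enumerate(df.to_dict("records")):
        try:
            vas = float(row["vas"])
            if math.isnan(vas):
                raise ValueError("VAS is missing")
            ca125_value = row.get("ca125_value")
            if ca125_value is not None and (isinstance(ca125_value, float) and math.isnan(ca125_value)):
                ca125_value = None
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                lap_result=_parse_optional_binary(row.get("lap_result"), "lap_result"),
                cec_count=int(row["cec_count"]),
                ca125_value=None if ca125_value is None else float(ca125_value),
                ca125_positive=_parse_optional_binary(row.get("ca125_positive"), "ca125_positive"),
                vas=vas,
                phase=Phase(str(row["phase"])),
                worsened_6mo=bool(int(row["worsened_6mo"])),
                treated=bool(int(row["treated"])),
                group_label=GroupLabel(str(row["group_label"])),
                adenomyosis=bool(int(row.get("adenomyosis", 0) or 0)),
                true_status=_parse_optional_binary(row.get("true_status"), "true_status"),
            )
            rec.validate(ca125_threshold)
            records.append(rec)
        except (ValueError, KeyError, TypeError) as exc:
            row_errors[i] = str(exc)
    if row_errors:
        preview = "; ".join(f"row {i}: {m}" for i, m in list(row_errors.items())[:5])
        raise CohortValidationError(
            f"{len(row_errors)} invalid row(s): {preview}", row_errors
        )

    has_truth = any(r.true_status is not None for r in records)
    if provenance == "observed" and has_truth:
        provenance = "synthetic"  # truth column only exists in simulated data
    return Cohort(records=tuple(records), provenance=provenance)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as plain CSV; round-trips bit-exactly through read_cohort."""
    df = cohort.to_frame()
    if cohort.provenance != "synthetic":
        df = df.drop(columns=["true_status"])
    # Optional 0/1 columns as nullable ints so blanks (not "nan") land in the CSV
    for col in _OPTIONAL_INT:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    df.to_csv(path, index=False)


def config_digest(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
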