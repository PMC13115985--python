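"""Descriptive layer: detection rates, mean counts, stratified summaries,
and cell-size subtype proportions.

These are the model-free statistics of the study — e.g. the CEC detection
rate among untreated surgically confirmed patients, its counterpart among
controls, the rise of detection with dysmenorrhea severity, and the
predominance of small (< 5 um) cells in disease.  Everything here is plain
counting; the latent class machinery lives elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import Cohort, PatientRecord, binarize_cec

__all__ = ["GroupSummary", "detection_rate", "stratified_summary",
           "subtype_proportions", "render_rate", "summaries_frame"]


@dataclass(frozen=True)
class GroupSummary:
    """Counts and rates for one patient group."""

    label: str
    n: int
    n_positive: int
    detection_rate: float
    mean_count: float
    sd_count: float

    def __post_init__(self):
        if not (0 <= self.n_positive <= self.n):
            raise ValueError("n_positive must lie in [0, n]")

    def render(self) -> str:
        """Study-style text: '64.0% (55/86)'."""
        return render_rate(self.n_positive, self.n)


def render_rate(numerator: int, denominator: int) -> str:
    return f"{100.0 * numerator / denominator:.1f}% ({numerator}/{denominator})"


def _default_positivity(r: PatientRecord) -> int:
    return binarize_cec(r.cec_count)


def detection_rate(
    records: Cohort | Sequence[PatientRecord],
    positivity: Callable[[PatientRecord], int] = _default_positivity,
    label: str = "group",
) -> GroupSummary:
    """Positivity rate and mean cell count over a group of patients.

    The mean count runs over ALL patients in the group, zeros included, to
    match how the study pairs detection rates with mean counts per 6 mL.
    """
    recs = list(records)
    if not recs:
        raise ValueError("empty group: detection rate undefined")
    pos = sum(int(positivity(r)) for r in recs)
    counts = np.array([r.cec_count for r in recs], dtype=float)
    return GroupSummary(
        label=label,
        n=len(recs),
        n_positive=pos,
        detection_rate=pos / len(recs),
        mean_count=float(counts.mean()),
        sd_count=float(counts.std(ddof=1)) if len(recs) > 1 else 0.0,
    )


def stratified_summary(
    cohort: Cohort | Sequence[PatientRecord],
    strata: Callable[[PatientRecord], str] | Mapping[str, Callable[[PatientRecord], bool]],
    positivity: Callable[[PatientRecord], int] = _default_positivity,
) -> list[GroupSummary]:
    """One GroupSummary per stratum; the strata must partition the cohort.

    ``strata`` is either a labelling function (a partition by construction)
    or a mapping of label -> predicate, in which case every record must match
    exactly one predicate (overlap or gaps raise).
    """
    recs = list(cohort)
    groups: dict[str, list[PatientRecord]] = {}
    if callable(strata):
        for r in recs:
            groups.setdefault(str(strata(r)), []).append(r)
    else:
        for r in recs:
            hits = [lb for lb, pred in strata.items() if pred(r)]
            if len(hits) != 1:
                raise ValueError(
                    f"record {r.patient_id} matches {len(hits)} strata; "
                    "strata must partition the cohort")
            groups.setdefault(hits[0], []).append(r)
    out = [detection_rate(g, positivity, label=lb) for lb, g in groups.items()]
    assert sum(s.n for s in out) == len(recs)
    return out


def subtype_proportions(
    small_counts: Iterable[int],
    large_counts: Iterable[int],
    group: str = "group",
) -> float:
    """Pooled fraction of small (< 5 um) cells among all detected cells."""
    small = int(np.sum(np.fromiter(small_counts, dtype=int)))
    large = int(np.sum(np.fromiter(large_counts, dtype=int)))
    if small < 0 or large < 0:
        raise ValueError("counts must be non-negative")
    total = small + large
    if total == 0:
        raise ValueError(f"no detected cells in group {group!r}: proportion undefined")
    return small / total


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "label": s.label, "n": s.n, "n_positive": s.n_positive,
        "detection_rate": round(s.detection_rate, 3),
        "mean_count": s.mean_count, "sd_count": s.sd_count,
        "rendered": s.render(),
    } for s in summaries])
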