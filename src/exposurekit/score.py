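"""The EXPoSURE composite severity score.

One point is allocated for each of six characteristics present in a patient
record: positive PD-L1 expression, positive p63 expression, a confirmed EGFR
mutation (any tested exon), advanced clinical stage (TNM III or IV), presence
of any comorbidity, and a histological subtype with increased aggressiveness
(small cell carcinoma or pulmonary neuroendocrine tumor).  The point total is
recoded into an ordinal class: low (0-1), medium (2-3), high (>=4).

With all six components active the theoretical maximum is 6 points; the high
class is defined as "4 or more" so the three-class recoding is unaffected.
Any component can be dropped for sensitivity analysis via ``components=``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .cohort import Cohort, PatientRecord

__all__ = [
    "COMPONENT_NAMES",
    "ScoreComponents",
    "ScoreResult",
    "ScoringError",
    "component_flags",
    "total_score",
    "score_record",
    "score_cohort",
]

COMPONENT_NAMES: tuple[str, ...] = (
    "pdl1_positive",
    "p63_positive",
    "egfr_mutated",
    "advanced_stage",
    "has_comorbidity",
    "aggressive_histology",
)

#: Ordinal classes in severity order.
SCORE_CLASSES: tuple[str, str, str] = ("low", "medium", "high")


class ScoringError(ValueError):
    """A record cannot be scored (missing required field)."""


@dataclass(frozen=True)
class ScoreComponents:
    """The six binary components; each derives from one record field."""

    pdl1_positive: bool
    p63_positive: bool
    egfr_mutated: bool
    advanced_stage: bool
    has_comorbidity: bool
    aggressive_histology: bool

    def flags(self, components: tuple[str, ...] = COMPONENT_NAMES) -> tuple[bool, ...]:
        return tuple(getattr(self, name) for name in components)


@dataclass(frozen=True)
class ScoreResult:
    """Point total and ordinal class for one patient."""

    points: int
    score_class: str


def component_flags(record: PatientRecord) -> ScoreComponents:
    """Derive the six component flags from a patient record."""
    for name in ("pdl1", "p63", "egfr", "tnm_stage", "comorbidity", "diagnostic_group"):
        if getattr(record, name, None) is None:
            raise ScoringError(f"record {record.patient_id}: missing {name}")
    return ScoreComponents(
        pdl1_positive=record.pdl1 == "positive",
        p63_positive=record.p63 == "positive",
        egfr_mutated=record.egfr != "none",
        advanced_stage=record.tnm_stage in ("III", "IV"),
        has_comorbidity=record.comorbidity != "none",
        aggressive_histology=record.diagnostic_group in ("G2", "G3"),
    )


def classify_points(points: int) -> str:
    if points <= 1:
        return "low"
    if points <= 3:
        return "medium"
    return "high"


def total_score(
    components: ScoreComponents, include: tuple[str, ...] = COMPONENT_NAMES
) -> ScoreResult:
    """Sum the component flags and recode into low/medium/high.

    ``include`` restricts the sum to a subset of components (sensitivity
    analysis); by default all six count one point each.
    """
    points = int(sum(components.flags(include)))
    return ScoreResult(points=points, score_class=classify_points(points))


def score_record(record: PatientRecord, include: tuple[str, ...] = COMPONENT_NAMES) -> ScoreResult:
    return total_score(component_flags(record), include)


def score_cohort(
    cohort: Cohort, include: tuple[str, ...] = COMPONENT_NAMES
) -> tuple[dict[str, ScoreResult], dict[str, int]]:
    """Score every record; return per-record results and class frequencies.

    Returns
    -------
    results
        ``patient_id -> ScoreResult`` in cohort order.
    summary
        Counts per ordinal class, in severity order (low, medium, high);
        classes absent from the cohort are omitted for an empty cohort and
        reported as 0 otherwise.
    """
    results: dict[str, ScoreResult] = {}
    errors: list[str] = []
    for record in cohort:
        try:
            results[record.patient_id] = score_record(record, include)
        except ScoringError as exc:
            errors.append(str(exc))
    if errors:
        raise ScoringError("; ".join(errors))
    if not results:
        return results, {}
    counts = Counter(r.score_class for r in results.values())
    summary = {cls: counts.get(cls, 0) for cls in SCORE_CLASSES}
    return results, summary
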