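"""Patient-level cohort containers, controlled vocabularies and cross-tabulation.

The analysis unit is a :class:`PatientRecord` holding the categorical and
numeric attributes collected for each lung-cancer patient (demographics,
smoking, comorbidity, occupational exposure, histopathological diagnostic
group, TNM stage and the molecular markers p63, PD-L1, EGFR, Ki-67).  The
inferential unit is a :class:`ContingencyTable`, a labelled r x c count matrix
with margins.  Tables and record collections convert losslessly into one
another through :func:`crosstab` and :func:`expand_table`, which is what lets
published cross-tabulations be re-analysed without patient-level data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VOCABULARIES",
    "HISTOLOGY_BY_GROUP",
    "AGE_CLASSES",
    "COHORT_COLUMNS",
    "PatientRecord",
    "Cohort",
    "ContingencyTable",
    "CohortError",
    "SchemaError",
    "RecordValidationError",
    "derive_age_class",
    "read_cohort_csv",
    "write_cohort_csv",
    "crosstab",
    "expand_table",
    "table_from_pairs",
]


class CohortError(ValueError):
    """Base class for cohort construction/validation failures."""


class SchemaError(CohortError):
    """A required column is missing or the file layout is unusable."""


class RecordValidationError(CohortError):
    """A row carries a value outside the controlled vocabulary or range."""


#: Controlled vocabularies, in the display order used by the study's tables
#: (the order matters: cross-tabulations reproduce published tables
#: cell-for-cell only if labels keep this order).
VOCABULARIES: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "residence": ("rural", "urban"),
    "smoker": ("no", "yes"),
    "comorbidity": ("none", "asthma", "copd", "heart_disease", "diabetes"),
    "occupational_exposure": ("no", "yes"),
    "diagnostic_group": ("G1a", "G1b", "G2", "G3"),
    "tnm_stage": ("II", "III", "IV"),
    "p63": ("negative", "positive"),
    "pdl1": ("negative", "positive"),
    "egfr": ("none", "exon18", "exon19", "exon20", "exon21"),
}

#: Fixed one-to-one mapping between diagnostic group and histological type.
HISTOLOGY_BY_GROUP: dict[str, str] = {
    "G1a": "adenocarcinoma",
    "G1b": "squamous_cell_carcinoma",
    "G2": "small_cell_carcinoma",
    "G3": "neuroendocrine_tumor",
}

#: Age classes partition the age axis at 50 and 65 years.
AGE_CLASSES: tuple[str, str, str] = ("under50", "from50to64", "from65")

#: Canonical CSV column order (schema v1).
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "sex",
    "residence",
    "smoker",
    "comorbidity",
    "occupational_exposure",
    "age_years",
    "diagnostic_group",
    "tnm_stage",
    "p63",
    "pdl1",
    "egfr",
    "ki67_percent",
)

#: Vocabularies for variables derived at cross-tabulation time.
_DERIVED_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "age_class": AGE_CLASSES,
    "histology": tuple(HISTOLOGY_BY_GROUP[g] for g in VOCABULARIES["diagnostic_group"]),
    "egfr_binary": ("negative", "positive"),
    "comorbidity_any": ("no", "yes"),
    "exposure_class": ("low", "medium", "high"),
}


def derive_age_class(age_years: int) -> str:
    """Map an age in years to the study's three age classes.

    Under 50 years -> ``under50``; 50-64 inclusive -> ``from50to64``;
    65 and above -> ``from65``.
    """
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    if age_years < 50:
        return "under50"
    if age_years < 65:
        return "from50to64"
    return "from65"


@dataclass(frozen=True)
class PatientRecord:
    """One patient's attributes; categorical fields use the controlled vocabularies."""

    patient_id: str
    sex: str
    residence: str
    smoker: str
    comorbidity: str
    occupational_exposure: str
    diagnostic_group: str
    tnm_stage: str
    p63: str
    pdl1: str
    egfr: str
    age_years: int | None = None
    ki67_percent: float | None = None

    def __post_init__(self) -> None:
        for name, vocab in VOCABULARIES.items():
            value = getattr(self, name)
            if value not in vocab:
                raise RecordValidationError(
                    f"{name}={value!r} not in vocabulary {vocab}"
                )
        if self.age_years is not None and not (18 <= self.age_years <= 120):
            raise RecordValidationError(
                f"age_years={self.age_years} outside plausible range [18, 120]"
            )
        if self.ki67_percent is not None and not (0.0 <= self.ki67_percent <= 100.0):
            raise RecordValidationError(
                f"ki67_percent={self.ki67_percent} outside [0, 100]"
            )

    @property
    def histology(self) -> str:
        return HISTOLOGY_BY_GROUP[self.diagnostic_group]

    @property
    def age_class(self) -> str | None:
        if self.age_years is None:
            return None
        return derive_age_class(self.age_years)


@dataclass
class Cohort:
    """An ordered collection of :class:`PatientRecord` with unique patient ids."""

    records: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient_id values: {dupes}")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {f.name: getattr(r, f.name) for f in dc_fields(PatientRecord)}
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Cohort":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns
                   and c not in ("age_years", "ki67_percent")]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        records = []
        for idx, row in df.iterrows():
            records.append(_record_from_mapping(dict(row), row_number=idx))
        return cls(records)


def _clean_categorical(name: str, raw: object, row_number) -> str:
    vocab = VOCABULARIES[name]
    value = str(raw).strip()
    lowered = value.lower()
    for label in vocab:
        if lowered == label.lower():
            return label
    raise RecordValidationError(
        f"row {row_number}: {name}={value!r} is not one of {vocab}"
    )


def _record_from_mapping(mapping: dict, row_number) -> PatientRecord:
    def _is_missing(v: object) -> bool:
        if v is None:
            return True
        if isinstance(v, float) and np.isnan(v):
            return True
        return isinstance(v, str) and v.strip() == ""

    kwargs: dict[str, object] = {"patient_id": str(mapping.get("patient_id", "")).strip()}
    if not kwargs["patient_id"]:
        raise RecordValidationError(f"row {row_number}: empty patient_id")
    for name in VOCABULARIES:
        raw = mapping.get(name)
        if _is_missing(raw):
            raise RecordValidationError(f"row {row_number}: missing value for {name}")
        kwargs[name] = _clean_categorical(name, raw, row_number)
    for name, caster in (("age_years", int), ("ki67_percent", float)):
        raw = mapping.get(name)
        if _is_missing(raw):
            kwargs[name] = None
        else:
            try:
                kwargs[name] = caster(float(raw))
            except (TypeError, ValueError) as exc:
                raise RecordValidationError(
                    f"row {row_number}: {name}={raw!r} is not numeric"
                ) from exc
    try:
        return PatientRecord(**kwargs)  # type: ignore[arg-type]
    except RecordValidationError as exc:
        raise RecordValidationError(f"row {row_number}: {exc}") from exc


def read_cohort_csv(path: str | Path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a patient-level cohort from a comma-separated UTF-8 file.

    Parameters
    ----------
    path
        CSV file with a header row.  Empty strings denote missing values for
        the optional columns ``age_years`` and ``ki67_percent``.
    schema
        Optional mapping from canonical column name to the column name used in
        the file, for files that follow a different naming convention.

    Rows with labels outside the controlled vocabularies are rejected with a
    row-level error; they are never silently coerced.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: no header row")
        colmap = {c: (schema or {}).get(c, c) for c in COHORT_COLUMNS}
        required = [c for c in COHORT_COLUMNS if c not in ("age_years", "ki67_percent")]
        missing = [colmap[c] for c in required if colmap[c] not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {missing}")
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            mapping = {canon: row.get(actual) for canon, actual in colmap.items()}
            records.append(_record_from_mapping(mapping, row_number=i))
    return Cohort(records)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV; reading it back reproduces the cohort field-for-field."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in cohort:
            row = []
            for col in COHORT_COLUMNS:
                value = getattr(r, col)
                if value is None:
                    value = ""
                row.append(value)
            writer.writerow(row)


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled r x c count matrix with margins; the inferential unit.

    ``counts[i, j]`` is the number of patients with row label ``row_labels[i]``
    and column label ``col_labels[j]``.  Zero rows/columns are retained so the
    table mirrors the declared vocabulary; statistical routines drop them.
    """

    row_var: str
    col_var: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = self.to_array()
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("a contingency table needs at least 2 rows and 2 columns")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_array(
        cls,
        counts: Sequence[Sequence[int]] | np.ndarray,
        row_labels: Sequence[str],
        col_labels: Sequence[str],
        row_var: str = "rows",
        col_var: str = "cols",
    ) -> "ContingencyTable":
        arr = np.asarray(counts, dtype=int)
        return cls(
            row_var=row_var,
            col_var=col_var,
            row_labels=tuple(row_labels),
            col_labels=tuple(col_labels),
            counts=tuple(tuple(int(v) for v in row) for row in arr),
        )

    def to_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def n(self) -> int:
        return int(self.to_array().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    @property
    def row_margins(self) -> np.ndarray:
        return self.to_array().sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.to_array().sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.to_array(), index=list(self.row_labels), columns=list(self.col_labels)
        )


def _variable_values(cohort: Cohort, name: str, scores=None) -> list[str]:
    """Per-record values for a raw or derived categorical variable."""
    if name in VOCABULARIES:
        return [getattr(r, name) for r in cohort]
    if name == "age_class":
        values = []
        for r in cohort:
            if r.age_years is None:
                raise CohortError(f"record {r.patient_id}: age missing, cannot class")
            values.append(derive_age_class(r.age_years))
        return values
    if name == "histology":
        return [r.histology for r in cohort]
    if name == "egfr_binary":
        return ["negative" if r.egfr == "none" else "positive" for r in cohort]
    if name == "comorbidity_any":
        return ["no" if r.comorbidity == "none" else "yes" for r in cohort]
    if name == "exposure_class":
        # deferred import: scoring depends on this module
        from .score import score_record

        return [score_record(r).score_class for r in cohort]
    raise CohortError(f"unknown variable name: {name!r}")


def variable_vocabulary(name: str) -> tuple[str, ...]:
    """Declared label order for a raw or derived categorical variable."""
    if name in VOCABULARIES:
        return VOCABULARIES[name]
    if name in _DERIVED_VOCABULARIES:
        return _DERIVED_VOCABULARIES[name]
    raise CohortError(f"unknown variable name: {name!r}")


def crosstab(cohort: Cohort, row_var: str, col_var: str) -> ContingencyTable:
    """Cross-tabulate two categorical (raw or derived) cohort variables.

    Labels follow the declared vocabulary order; zero rows/columns are kept.
    Derived variables: ``age_class``, ``histology``, ``egfr_binary``,
    ``comorbidity_any`` and ``exposure_class`` (the composite severity class).
    """
    rows = _variable_values(cohort, row_var)
    cols = _variable_values(cohort, col_var)
    row_labels = variable_vocabulary(row_var)
    col_labels = variable_vocabulary(col_var)
    return table_from_pairs(
        zip(rows, cols), row_labels, col_labels, row_var=row_var, col_var=col_var
    )


def table_from_pairs(
    pairs: Iterable[tuple[str, str]],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    row_var: str = "rows",
    col_var: str = "cols",
) -> ContingencyTable:
    """Build a contingency table from (row_label, col_label) observations."""
    ri = {label: i for i, label in enumerate(row_labels)}
    ci = {label: j for j, label in enumerate(col_labels)}
    counts = np.zeros((len(ri), len(ci)), dtype=int)
    for r, c in pairs:
        if r not in ri:
            raise CohortError(f"row label {r!r} not in {tuple(row_labels)}")
        if c not in ci:
            raise CohortError(f"column label {c!r} not in {tuple(col_labels)}")
        counts[ri[r], ci[c]] += 1
    return ContingencyTable.from_array(counts, row_labels, col_labels, row_var, col_var)


def expand_table(table: ContingencyTable) -> list[tuple[str, str]]:
    """Expand a table into its multiset of (row_label, col_label) pairs.

    Row-major, deterministic order; ``table_from_pairs(expand_table(t))``
    reproduces ``t`` exactly, which is how published cross-tabulations are
    turned back into analysable observations.
    """
    pairs: list[tuple[str, str]] = []
    arr = table.to_array()
    for i, rl in enumerate(table.row_labels):
        for j, cl in enumerate(table.col_labels):
            pairs.extend([(rl, cl)] * int(arr[i, j]))
    return pairs
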