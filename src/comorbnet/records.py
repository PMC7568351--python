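"""Diagnosis records: the one-row-per-patient-visit-code input table."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from ._icd import is_valid_code

CSV_COLUMNS = ["patient_id", "visit_id", "icd10_code", "sex", "age_years", "region"]

SEXES = {"male", "female"}
REGIONS = {"urban", "rural"}
MAX_AGE = 18


@dataclass(frozen=True, slots=True)
class DiagnosisRecord:
    """A single diagnosis assigned to a patient at one hospital visit."""

    patient_id: str
    visit_id: str
    icd10_code: str
    sex: str
    age_years: int
    region: str

    def validate(self) -> None:
        if not is_valid_code(self.icd10_code):
            raise ValueError(f"invalid ICD-10 code {self.icd10_code!r}")
        if self.sex not in SEXES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.region not in REGIONS:
            raise ValueError(f"invalid region {self.region!r}")
        if not 0 <= self.age_years <= MAX_AGE:
            raise ValueError(f"age_years {self.age_years} outside 0-{MAX_AGE}")


class RecordFormatError(ValueError):
    """The input table is missing required columns."""


class RecordValidationError(ValueError):
    """One or more rows violate the record schema; carries row numbers."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {i}: {msg}" for i, msg in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"invalid diagnosis rows: {lines}{more}")


def load_records(path: str | Path) -> list[DiagnosisRecord]:
    """Read and validate a diagnosis CSV.

    Raises :class:`RecordFormatError` if columns are missing and
    :class:`RecordValidationError` naming the offending rows (1-based,
    counting the header as row 1) if any row fails validation.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"missing columns {missing} in {path}")
    records: list[DiagnosisRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = DiagnosisRecord(
                patient_id=str(row.patient_id),
                visit_id=str(row.visit_id),
                icd10_code=str(row.icd10_code),
                sex=str(row.sex),
                age_years=int(row.age_years),
                region=str(row.region),
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            problems.append((i, str(exc)))
            continue
        records.append(rec)
    if problems:
        raise RecordValidationError(problems)
    return records


def write_records(records: Iterable[DiagnosisRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical header."""
    df = pd.DataFrame(
        [{c: getattr(r, c) for c in CSV_COLUMNS} for r in records],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
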