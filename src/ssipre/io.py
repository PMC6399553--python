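"""CSV interchange for lab measurements and patient records.

Formats (plain CSV, header required):

* labs:     ``patient_id,test_name,day,value`` — ``day`` is an integer number
  of days before surgery (0 = day of surgery).
* patients: ``patient_id,age,sex,ssi`` — ``sex`` and ``ssi`` are 0/1 codes.

Malformed rows are reported with their 1-based file line number so problems
in exported hospital extracts can be located directly.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .catalog import TestCatalogEntry
    from .synth import LabMeasurement, PatientRecord

LABS_HEADER = ["patient_id", "test_name", "day", "value"]
PATIENTS_HEADER = ["patient_id", "age", "sex", "ssi"]


class CsvFormatError(ValueError):
    """A malformed row, reported with its file line number."""


def write_labs_csv(measurements: Sequence["LabMeasurement"], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LABS_HEADER)
        for m in measurements:
            writer.writerow([m.patient_id, m.test_name, m.day, repr(m.value)])


def read_labs_csv(
    path: str | Path, catalog: Sequence["TestCatalogEntry"] | None = None
) -> list["LabMeasurement"]:
    """Read lab measurements, optionally validating test names against a catalog."""
    from .synth import LabMeasurement

    known = {e.test_name for e in catalog} if catalog is not None else None
    out: list[LabMeasurement] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != LABS_HEADER:
            raise CsvFormatError(f"{path}: line 1: expected header {','.join(LABS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise CsvFormatError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            pid, test, day_s, value_s = row
            try:
                day = int(day_s)
                value = float(value_s)
            except ValueError as exc:
                raise CsvFormatError(f"{path}: line {lineno}: {exc}") from exc
            if known is not None and test not in known:
                raise CsvFormatError(f"{path}: line {lineno}: unknown test name {test!r}")
            out.append(LabMeasurement(patient_id=pid, test_name=test, day=day, value=value))
    return out


def write_patients_csv(patients: Sequence["PatientRecord"], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENTS_HEADER)
        for p in patients:
            writer.writerow([p.patient_id, repr(p.age), p.sex, p.ssi])


def read_patients_csv(path: str | Path) -> list["PatientRecord"]:
    from .synth import PatientRecord

    out: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != PATIENTS_HEADER:
            raise CsvFormatError(f"{path}: line 1: expected header {','.join(PATIENTS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise CsvFormatError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            pid, age_s, sex_s, ssi_s = row
            try:
                out.append(
                    PatientRecord(
                        patient_id=pid, age=float(age_s), sex=int(sex_s), ssi=int(ssi_s)
                    )
                )
            except ValueError as exc:
                raise CsvFormatError(f"{path}: line {lineno}: {exc}") from exc
    return out
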