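"""Readers and writers for the four diary CSV tables.

Files are UTF-8 comma-separated with a header row.  Booleans are written
as ``true``/``false``; missing values are empty cells; timestamps are
ISO 8601 without timezone.
"""

from __future__ import annotations

import csv
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Union

from .model import (
    DailyEntry,
    DiaryCollection,
    DiaryValidationError,
    EntryKind,
    HeadacheAttack,
    MedicationIntake,
    PriorDiagnosis,
    Sex,
    UserProfile,
    validate_collection,
)

USERS_COLUMNS = ["user_id", "sex", "age", "prior_diagnosis", "first_use_date"]
ATTACKS_COLUMNS = [
    "attack_id", "user_id", "start", "end", "max_intensity",
    "unilateral", "throbbing", "worse_with_activity", "nausea", "vomitus",
    "photophobia", "phonophobia", "aura",
]
MEDICATIONS_COLUMNS = ["user_id", "drug_name", "dose", "intake_time",
                       "migraine_specific"]
ENTRIES_COLUMNS = ["user_id", "entry_date", "entry_kind"]

_ATTACK_FLAGS = ATTACKS_COLUMNS[5:]


def _parse_bool(value: str, *, table: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v == "true":
        return True
    if v == "false":
        return False
    raise DiaryValidationError(
        "malformed boolean", f"{column}={value!r} is not true/false",
        table=table, row=row)


def _parse_opt_bool(value: str, *, table: str, row: int,
                    column: str) -> Optional[bool]:
    if value.strip() == "":
        return None
    return _parse_bool(value, table=table, row=row, column=column)


def _parse_datetime(value: str, *, table: str, row: int,
                    column: str) -> datetime:
    try:
        return datetime.fromisoformat(value.strip())
    except ValueError:
        raise DiaryValidationError(
            "malformed timestamp", f"{column}={value!r} is not ISO 8601",
            table=table, row=row) from None


def _parse_date(value: str, *, table: str, row: int, column: str) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError:
        raise DiaryValidationError(
            "malformed date", f"{column}={value!r} is not an ISO date",
            table=table, row=row) from None


def _read_rows(path: Union[str, Path], columns: list[str], table: str):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != columns:
            raise DiaryValidationError(
                "bad header",
                f"expected columns {columns}, got {reader.fieldnames}",
                table=table)
        for i, raw in enumerate(reader, start=1):
            if None in raw or any(v is None for v in raw.values()):
                raise DiaryValidationError(
                    "bad row shape", "wrong number of fields",
                    table=table, row=i)
            yield i, raw


def read_diary(users_path, attacks_path, medications_path,
               entries_path) -> DiaryCollection:
    """Read and validate the four diary tables into a collection.

    Missing sex / age / prior_diagnosis cells map to
    ``unknown`` / ``None`` / ``unknown``.  Raises
    :class:`~headachediary.model.DiaryValidationError` naming the violated
    rule, table, and 1-based row for any malformed input.
    """
    users = []
    for i, raw in _read_rows(users_path, USERS_COLUMNS, "users"):
        sex_raw = raw["sex"].strip().lower()
        try:
            sex = Sex(sex_raw) if sex_raw else Sex.UNKNOWN
        except ValueError:
            raise DiaryValidationError(
                "malformed sex", f"sex={raw['sex']!r}", table="users",
                row=i) from None
        age: Optional[int] = None
        if raw["age"].strip():
            try:
                age = int(raw["age"])
            except ValueError:
                raise DiaryValidationError(
                    "malformed age", f"age={raw['age']!r}", table="users",
                    row=i) from None
        dx_raw = raw["prior_diagnosis"].strip().lower()
        try:
            dx = PriorDiagnosis(dx_raw) if dx_raw else PriorDiagnosis.UNKNOWN
        except ValueError:
            raise DiaryValidationError(
                "malformed prior_diagnosis",
                f"prior_diagnosis={raw['prior_diagnosis']!r}",
                table="users", row=i) from None
        users.append(UserProfile(
            user_id=raw["user_id"],
            sex=sex,
            age=age,
            prior_diagnosis=dx,
            first_use_date=_parse_date(raw["first_use_date"], table="users",
                                       row=i, column="first_use_date"),
        ))

    attacks = []
    for i, raw in _read_rows(attacks_path, ATTACKS_COLUMNS, "attacks"):
        try:
            intensity = int(raw["max_intensity"])
        except ValueError:
            raise DiaryValidationError(
                "malformed intensity",
                f"max_intensity={raw['max_intensity']!r}",
                table="attacks", row=i) from None
        flags = {f: _parse_bool(raw[f], table="attacks", row=i, column=f)
                 for f in _ATTACK_FLAGS}
        attacks.append(HeadacheAttack(
            attack_id=raw["attack_id"],
            user_id=raw["user_id"],
            start=_parse_datetime(raw["start"], table="attacks", row=i,
                                  column="start"),
            end=_parse_datetime(raw["end"], table="attacks", row=i,
                                column="end"),
            max_intensity=intensity,
            **flags,
        ))

    medications = []
    for i, raw in _read_rows(medications_path, MEDICATIONS_COLUMNS,
                             "medications"):
        medications.append(MedicationIntake(
            user_id=raw["user_id"],
            drug_name=raw["drug_name"],
            dose=raw["dose"],
            intake_time=_parse_datetime(raw["intake_time"],
                                        table="medications", row=i,
                                        column="intake_time"),
            migraine_specific=_parse_opt_bool(
                raw["migraine_specific"], table="medications", row=i,
                column="migraine_specific"),
        ))

    entries = []
    for i, raw in _read_rows(entries_path, ENTRIES_COLUMNS, "entries"):
        kind_raw = raw["entry_kind"].strip().lower()
        try:
            kind = EntryKind(kind_raw)
        except ValueError:
            raise DiaryValidationError(
                "malformed entry_kind", f"entry_kind={raw['entry_kind']!r}",
                table="entries", row=i) from None
        entries.append(DailyEntry(
            user_id=raw["user_id"],
            entry_date=_parse_date(raw["entry_date"], table="entries",
                                   row=i, column="entry_date"),
            entry_kind=kind,
        ))

    collection = DiaryCollection(users=users, attacks=attacks,
                                 medications=medications, entries=entries)
    validate_collection(collection)
    return collection


def _fmt_bool(v: Optional[bool]) -> str:
    if v is None:
        return ""
    return "true" if v else "false"


def write_diary(collection: DiaryCollection, out_dir) -> dict[str, Path]:
    """Write the collection to ``users/attacks/medications/entries.csv``.

    Round-trips exactly through :func:`read_diary`, including missingness.
    Returns a mapping of table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.csv"
             for name in ("users", "attacks", "medications", "entries")}

    with paths["users"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(USERS_COLUMNS)
        for u in collection.users:
            w.writerow([
                u.user_id,
                "" if u.sex is Sex.UNKNOWN else u.sex.value,
                "" if u.age is None else u.age,
                "" if u.prior_diagnosis is PriorDiagnosis.UNKNOWN
                else u.prior_diagnosis.value,
                u.first_use_date.isoformat(),
            ])

    with paths["attacks"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ATTACKS_COLUMNS)
        for a in collection.attacks:
            w.writerow([
                a.attack_id, a.user_id,
                a.start.isoformat(), a.end.isoformat(), a.max_intensity,
                _fmt_bool(a.unilateral), _fmt_bool(a.throbbing),
                _fmt_bool(a.worse_with_activity), _fmt_bool(a.nausea),
                _fmt_bool(a.vomitus), _fmt_bool(a.photophobia),
                _fmt_bool(a.phonophobia), _fmt_bool(a.aura),
            ])

    with paths["medications"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(MEDICATIONS_COLUMNS)
        for m in collection.medications:
            w.writerow([m.user_id, m.drug_name, m.dose,
                        m.intake_time.isoformat(),
                        _fmt_bool(m.migraine_specific)])

    with paths["entries"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ENTRIES_COLUMNS)
        for e in collection.entries:
            w.writerow([e.user_id, e.entry_date.isoformat(),
                        e.entry_kind.value])

    return paths
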