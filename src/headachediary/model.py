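"""Domain types and validation for the diary tables.

The diary consists of four flat tables: user profiles, headache attacks,
acute-medication intakes, and daily entries.  All timestamps are naive
local wall-clock times (ISO 8601); dates are compared as calendar dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Iterable, Optional


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class PriorDiagnosis(str, Enum):
    MIGRAINE = "migraine"
    OTHER = "other"
    NONE = "none"
    UNKNOWN = "unknown"


class EntryKind(str, Enum):
    HEADACHE = "headache"
    NO_HEADACHE = "no_headache"


class DiaryValidationError(ValueError):
    """A diary row or collection violates a named validation rule.

    Attributes
    ----------
    rule : str
        Short machine-readable name of the violated rule.
    table : str or None
        Which of the four tables the offending row belongs to.
    row : int or None
        1-based data-row index within that table (header excluded).
    """

    def __init__(self, rule: str, message: str, table: Optional[str] = None,
                 row: Optional[int] = None):
        self.rule = rule
        self.table = table
        self.row = row
        loc = ""
        if table is not None:
            loc = f" [{table}" + (f" row {row}" if row is not None else "") + "]"
        super().__init__(f"{rule}: {message}{loc}")


@dataclass(slots=True)
class UserProfile:
    user_id: str
    sex: Sex = Sex.UNKNOWN
    age: Optional[int] = None
    prior_diagnosis: PriorDiagnosis = PriorDiagnosis.UNKNOWN
    first_use_date: date = date(2000, 1, 1)


@dataclass(slots=True)
class HeadacheAttack:
    """One diary attack: interval, 0-10 maximal intensity, 8 symptom flags."""

    attack_id: str
    user_id: str
    start: datetime
    end: datetime
    max_intensity: int
    unilateral: bool = False
    throbbing: bool = False
    worse_with_activity: bool = False
    nausea: bool = False
    vomitus: bool = False
    photophobia: bool = False
    phonophobia: bool = False
    aura: bool = False


@dataclass(slots=True)
class MedicationIntake:
    user_id: str
    drug_name: str
    dose: str
    intake_time: datetime
    migraine_specific: Optional[bool] = None


@dataclass(slots=True)
class DailyEntry:
    user_id: str
    entry_date: date
    entry_kind: EntryKind


@dataclass(slots=True)
class DiaryCollection:
    users: list[UserProfile] = field(default_factory=list)
    attacks: list[HeadacheAttack] = field(default_factory=list)
    medications: list[MedicationIntake] = field(default_factory=list)
    entries: list[DailyEntry] = field(default_factory=list)

    def user_map(self) -> dict[str, UserProfile]:
        return {u.user_id: u for u in self.users}


def validate_attack(attack: HeadacheAttack, row: Optional[int] = None) -> None:
    """Check single-attack invariants; raise :class:`DiaryValidationError`."""
    if attack.end <= attack.start:
        raise DiaryValidationError(
            "end > start violated",
            f"attack {attack.attack_id!r} has end {attack.end.isoformat()} "
            f"<= start {attack.start.isoformat()}",
            table="attacks", row=row)
    if not (0 <= attack.max_intensity <= 10):
        raise DiaryValidationError(
            "intensity out of range",
            f"attack {attack.attack_id!r} max_intensity={attack.max_intensity} "
            "not in 0..10",
            table="attacks", row=row)


def validate_collection(collection: DiaryCollection) -> None:
    """Check all cross-record invariants of a :class:`DiaryCollection`.

    Rules enforced:

    * ``unique user_id`` and ``unique attack_id``
    * per-attack: ``end > start``, intensity in 0..10
    * ``overlapping attacks``: one user's attacks never intersect in time
    * ``unknown user_id``: every attack/medication/entry references a user
    * ``first_use after attack``: first_use_date <= earliest attack start
    * ``duplicate no_headache entry`` per (user, date)
    * ``headache entry without attack``: a headache entry date must be
      covered by some attack of that user
    """
    seen_users: set[str] = set()
    for i, u in enumerate(collection.users, start=1):
        if u.user_id in seen_users:
            raise DiaryValidationError(
                "unique user_id violated", f"duplicate user_id {u.user_id!r}",
                table="users", row=i)
        seen_users.add(u.user_id)
        if u.age is not None and u.age < 0:
            raise DiaryValidationError(
                "age out of range", f"user {u.user_id!r} age={u.age}",
                table="users", row=i)

    seen_attacks: set[str] = set()
    per_user: dict[str, list[tuple[datetime, datetime, str]]] = {}
    for i, a in enumerate(collection.attacks, start=1):
        validate_attack(a, row=i)
        if a.attack_id in seen_attacks:
            raise DiaryValidationError(
                "unique attack_id violated",
                f"duplicate attack_id {a.attack_id!r}", table="attacks", row=i)
        seen_attacks.add(a.attack_id)
        if a.user_id not in seen_users:
            raise DiaryValidationError(
                "unknown user_id", f"attack {a.attack_id!r} references "
                f"unknown user {a.user_id!r}", table="attacks", row=i)
        per_user.setdefault(a.user_id, []).append((a.start, a.end, a.attack_id))

    for uid, ivs in per_user.items():
        ivs.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise DiaryValidationError(
                    "overlapping attacks",
                    f"user {uid!r}: attacks {id1!r} and {id2!r} overlap "
                    f"({s1.isoformat()}..{e1.isoformat()} vs "
                    f"{s2.isoformat()}..{e2.isoformat()})",
                    table="attacks")

    users = collection.user_map()
    for uid, ivs in per_user.items():
        earliest = min(s for s, _, _ in ivs).date()
        if users[uid].first_use_date > earliest:
            raise DiaryValidationError(
                "first_use after attack",
                f"user {uid!r} first_use_date {users[uid].first_use_date} "
                f"is after earliest attack start {earliest}",
                table="users")

    for i, m in enumerate(collection.medications, start=1):
        if m.user_id not in seen_users:
            raise DiaryValidationError(
                "unknown user_id", f"medication row references unknown user "
                f"{m.user_id!r}", table="medications", row=i)

    attack_days: dict[str, set[date]] = {}
    for a in collection.attacks:
        days = attack_days.setdefault(a.user_id, set())
        d = a.start.date()
        while d <= a.end.date():
            days.add(d)
            d = date.fromordinal(d.toordinal() + 1)

    seen_no_headache: set[tuple[str, date]] = set()
    for i, e in enumerate(collection.entries, start=1):
        if e.user_id not in seen_users:
            raise DiaryValidationError(
                "unknown user_id", f"entry references unknown user "
                f"{e.user_id!r}", table="entries", row=i)
        if e.entry_kind is EntryKind.NO_HEADACHE:
            key = (e.user_id, e.entry_date)
            if key in seen_no_headache:
                raise DiaryValidationError(
                    "duplicate no_headache entry",
                    f"user {e.user_id!r} has two no_headache entries on "
                    f"{e.entry_date}", table="entries", row=i)
            seen_no_headache.add(key)
        else:
            if e.entry_date not in attack_days.get(e.user_id, ()):  # pragma: no branch
                raise DiaryValidationError(
                    "headache entry without attack",
                    f"user {e.user_id!r} headache entry on {e.entry_date} "
                    "is not covered by any attack", table="entries", row=i)
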