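"""Day expansion, 28-day monthly outcomes, diagnosis grouping, cohort selection.

All outcomes are day-level: a multi-day attack contributes every calendar
day its interval intersects.  A "month" is a 28-day window anchored at the
user's first day of app use; month 1 is the baseline month.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import pandas as pd

from .classifier import AttackClassification, HeadacheLabel
from .model import DiaryCollection, HeadacheAttack

DAYS_PER_MONTH = 28

#: ICHD-3 chronic migraine: headache >= 15 d/month with >= 8 migraine
#: d/month, applied as totals over the 90-day window (45 / 24).
CHRONIC_HEADACHE_DAYS_90 = 45
CHRONIC_MIGRAINE_DAYS_90 = 24
#: ICHD-3 migraine: at least 5 attacks.
EPISODIC_MIN_MIGRAINE_ATTACKS = 5
DIAGNOSIS_WINDOW_DAYS = 90


class DiagnosisLabel:
    EPISODIC_MIGRAINE = "EPISODIC_MIGRAINE"
    CHRONIC_MIGRAINE = "CHRONIC_MIGRAINE"
    OTHER = "OTHER"


@dataclass(slots=True)
class MonthlyOutcome:
    user_id: str
    month_index: int
    mhd: int
    mmd: int
    amd: int
    mean_headache_intensity: Optional[float]
    mean_migraine_intensity: Optional[float]


@dataclass(slots=True)
class DiagnosisGroup:
    user_id: str
    group: str


def attack_calendar_days(attack: HeadacheAttack) -> set[date]:
    """Every calendar date intersected by the attack interval."""
    days = set()
    d = attack.start.date()
    last = attack.end.date()
    while d <= last:
        days.add(d)
        d += timedelta(days=1)
    return days


def month_index(day: date, first_use_date: date) -> int:
    """1-based 28-day month index of ``day`` relative to first app use."""
    offset = (day - first_use_date).days
    if offset < 0:
        raise ValueError(f"date {day} precedes first_use_date {first_use_date}")
    return offset // DAYS_PER_MONTH + 1


def _day_table(collection: DiaryCollection,
               classifications: Sequence[AttackClassification]
               ) -> pd.DataFrame:
    """Per (user, date): max intensity over all attacks, migraine flag, and
    max intensity over migraine-labelled attacks."""
    labels = {c.attack_id: c.label for c in classifications}
    rows = []
    for a in collection.attacks:
        mig = labels[a.attack_id] is HeadacheLabel.MIGRAINE
        for d in sorted(attack_calendar_days(a)):
            rows.append((a.user_id, d, a.max_intensity, mig))
    if not rows:
        return pd.DataFrame(columns=["user_id", "date", "intensity",
                                     "is_migraine", "migraine_intensity"])
    df = pd.DataFrame(rows, columns=["user_id", "date", "intensity",
                                     "is_migraine"])
    df["migraine_intensity"] = df["intensity"].where(df["is_migraine"])
    agg = df.groupby(["user_id", "date"], as_index=False).agg(
        intensity=("intensity", "max"),
        is_migraine=("is_migraine", "any"),
        migraine_intensity=("migraine_intensity", "max"),
    )
    return agg


def compute_monthly_outcomes(collection: DiaryCollection,
                             classifications: Sequence[AttackClassification],
                             months: int) -> list[MonthlyOutcome]:
    """Per user x month (1..months): MHD, MMD, AMD and mean intensities.

    MHD counts days with any attack, MMD days with a MIGRAINE-labelled
    attack, AMD days with any acute-medication intake.  Monthly mean
    intensity is the mean over qualifying days of the day's maximal attack
    intensity; undefined (None) when the day count is zero.
    """
    if months < 1:
        raise ValueError("months must be >= 1")
    first_use = {u.user_id: u.first_use_date for u in collection.users}
    day_tab = _day_table(collection, classifications)

    per_cell: dict[tuple[str, int], dict] = {}
    for row in day_tab.itertuples(index=False):
        m = month_index(row.date, first_use[row.user_id])
        if not 1 <= m <= months:
            continue
        cell = per_cell.setdefault((row.user_id, m), {
            "hd": 0, "md": 0, "hi_sum": 0.0, "mi_sum": 0.0})
        cell["hd"] += 1
        cell["hi_sum"] += row.intensity
        if row.is_migraine:
            cell["md"] += 1
            cell["mi_sum"] += row.migraine_intensity

    med_days: dict[tuple[str, int], set[date]] = {}
    for m_int in collection.medications:
        d = m_int.intake_time.date()
        fu = first_use[m_int.user_id]
        if d < fu:
            continue
        m = month_index(d, fu)
        if 1 <= m <= months:
            med_days.setdefault((m_int.user_id, m), set()).add(d)

    out = []
    for u in collection.users:
        for m in range(1, months + 1):
            cell = per_cell.get((u.user_id, m))
            amd = len(med_days.get((u.user_id, m), ()))
            if cell is None:
                out.append(MonthlyOutcome(u.user_id, m, 0, 0, amd, None, None))
                continue
            hd, md = cell["hd"], cell["md"]
            out.append(MonthlyOutcome(
                u.user_id, m, hd, md, amd,
                cell["hi_sum"] / hd if hd else None,
                cell["mi_sum"] / md if md else None,
            ))
    return out


def _observed_days(collection: DiaryCollection) -> dict[str, set[date]]:
    """Calendar days covered by an entry or an attack, per user."""
    covered: dict[str, set[date]] = {u.user_id: set() for u in collection.users}
    for e in collection.entries:
        covered[e.user_id].add(e.entry_date)
    for a in collection.attacks:
        covered[a.user_id].update(attack_calendar_days(a))
    return covered


def assign_diagnosis_group(collection: DiaryCollection,
                           classifications: Sequence[AttackClassification],
                           *,
                           chronic_headache_days: int = CHRONIC_HEADACHE_DAYS_90,
                           chronic_migraine_days: int = CHRONIC_MIGRAINE_DAYS_90,
                           episodic_min_attacks: int = EPISODIC_MIN_MIGRAINE_ATTACKS,
                           window_days: int = DIAGNOSIS_WINDOW_DAYS
                           ) -> list[DiagnosisGroup]:
    """Diagnosis group per user from the first ``window_days`` days of use.

    CHRONIC_MIGRAINE: >= ``chronic_headache_days`` headache days of which
    >= ``chronic_migraine_days`` are migraine days.  Else
    EPISODIC_MIGRAINE when >= ``episodic_min_attacks`` migraine-labelled
    attacks started in the window.  Else OTHER.  Requires every user to be
    observed for at least ``window_days`` days.
    """
    first_use = {u.user_id: u.first_use_date for u in collection.users}
    covered = _observed_days(collection)
    for u in collection.users:
        days = covered[u.user_id]
        span = (max(days) - u.first_use_date).days + 1 if days else 0
        if span < window_days:
            raise ValueError(
                f"user {u.user_id!r} observed for {span} days; "
                f"{window_days} required for diagnosis grouping")

    labels = {c.attack_id: c.label for c in classifications}
    hd: dict[str, set[date]] = {u.user_id: set() for u in collection.users}
    md: dict[str, set[date]] = {u.user_id: set() for u in collection.users}
    n_migraine_attacks: dict[str, int] = {u.user_id: 0
                                          for u in collection.users}
    for a in collection.attacks:
        fu = first_use[a.user_id]
        end = fu + timedelta(days=window_days - 1)
        in_window = {d for d in attack_calendar_days(a) if fu <= d <= end}
        hd[a.user_id].update(in_window)
        if labels[a.attack_id] is HeadacheLabel.MIGRAINE:
            md[a.user_id].update(in_window)
            if fu <= a.start.date() <= end:
                n_migraine_attacks[a.user_id] += 1

    groups = []
    for u in collection.users:
        uid = u.user_id
        if (len(hd[uid]) >= chronic_headache_days
                and len(md[uid]) >= chronic_migraine_days):
            g = DiagnosisLabel.CHRONIC_MIGRAINE
        elif n_migraine_attacks[uid] >= episodic_min_attacks:
            g = DiagnosisLabel.EPISODIC_MIGRAINE
        else:
            g = DiagnosisLabel.OTHER
        groups.append(DiagnosisGroup(uid, g))
    return groups


def select_regular_users(collection: DiaryCollection,
                         months_required: int) -> list[str]:
    """Users with a diary entry or attack day on *every* calendar day from
    first use through day ``28 * months_required``."""
    if months_required < 1:
        raise ValueError("months_required must be >= 1")
    covered = _observed_days(collection)
    selected = []
    n_days = DAYS_PER_MONTH * months_required
    for u in collection.users:
        days = covered[u.user_id]
        start = u.first_use_date
        if all(start + timedelta(days=i) in days for i in range(n_days)):
            selected.append(u.user_id)
    return selected


def outcomes_to_frame(outcomes: Sequence[MonthlyOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.user_id, o.month_index, o.mhd, o.mmd, o.amd,
          o.mean_headache_intensity, o.mean_migraine_intensity)
         for o in outcomes],
        columns=["user_id", "month_index", "mhd", "mmd", "amd",
                 "mean_headache_intensity", "mean_migraine_intensity"])


def write_monthly_outcomes(outcomes: Sequence[MonthlyOutcome], path) -> None:
    """TSV with empty cells for undefined intensities."""
    outcomes_to_frame(outcomes).to_csv(path, sep="\t", index=False,
                                       float_format="%.6g")


def write_diagnosis_groups(groups: Sequence[DiagnosisGroup], path) -> None:
    pd.DataFrame([(g.user_id, g.group) for g in groups],
                 columns=["user_id", "group"]).to_csv(path, sep="\t",
                                                      index=False)
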