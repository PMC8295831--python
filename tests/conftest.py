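from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from headachediary.model import (
    DailyEntry,
    DiaryCollection,
    EntryKind,
    HeadacheAttack,
    MedicationIntake,
    PriorDiagnosis,
    Sex,
    UserProfile,
)


def make_attack(attack_id="a1", user_id="u1", start="2020-01-05 10:00",
                end="2020-01-05 14:00", max_intensity=5, **flags):
    return HeadacheAttack(
        attack_id=attack_id, user_id=user_id,
        start=datetime.fromisoformat(start), end=datetime.fromisoformat(end),
        max_intensity=max_intensity, **flags)


def fill_no_headache_entries(collection: DiaryCollection,
                             n_days: int) -> None:
    """Add a no_headache entry on every attack-free day of every user."""
    from headachediary.aggregate import attack_calendar_days

    covered: dict[str, set[date]] = {u.user_id: set()
                                     for u in collection.users}
    for a in collection.attacks:
        covered[a.user_id].update(attack_calendar_days(a))
    for u in collection.users:
        for i in range(n_days):
            d = u.first_use_date + timedelta(days=i)
            if d not in covered[u.user_id]:
                collection.entries.append(
                    DailyEntry(u.user_id, d, EntryKind.NO_HEADACHE))


def build_hand_fixture() -> DiaryCollection:
    """Three-user toy diary over 4 x 28 days (2020-01-01 .. 2020-04-21).

    Hand-computed per-user month-1 outcomes (see HAND_EXPECTED below):

    * u1 (prior migraine): five qualified migraine attacks over the first
      90 days (episodic), one TTH attack, one month-4 migraine.
    * u2 (no diagnosis): two TTH attacks only.
    * u3 (prior migraine): one TTH+probable attack (counted migraine via
      the prior diagnosis) and one aura override.
    """
    fu = date(2020, 1, 1)
    users = [
        UserProfile("u1", Sex.FEMALE, 35, PriorDiagnosis.MIGRAINE, fu),
        UserProfile("u2", Sex.MALE, 52, PriorDiagnosis.NONE, fu),
        UserProfile("u3", Sex.FEMALE, None, PriorDiagnosis.MIGRAINE, fu),
    ]
    mig = dict(unilateral=True, throbbing=True, nausea=True)
    attacks = [
        make_attack("a1", "u1", "2020-01-02 08:00", "2020-01-02 18:00", 7,
                    **mig),
        make_attack("a2", "u1", "2020-01-05 23:00", "2020-01-06 03:00", 5,
                    throbbing=True, photophobia=True, phonophobia=True),
        make_attack("a3", "u1", "2020-01-10 09:00", "2020-01-10 12:00", 3),
        make_attack("f1", "u1", "2020-02-03 10:00", "2020-02-03 16:00", 6,
                    **mig),
        make_attack("f2", "u1", "2020-02-14 10:00", "2020-02-14 16:00", 6,
                    **mig),
        make_attack("f3", "u1", "2020-03-02 10:00", "2020-03-02 16:00", 6,
                    **mig),
        make_attack("a4", "u1", "2020-04-05 10:00", "2020-04-05 16:00", 6,
                    **mig),
        make_attack("b1", "u2", "2020-01-03 09:00", "2020-01-03 15:00", 4),
        make_attack("b2", "u2", "2020-01-15 10:00", "2020-01-15 12:00", 2),
        make_attack("c1", "u3", "2020-01-04 10:00", "2020-01-04 15:00", 6,
                    unilateral=True, throbbing=True, photophobia=True),
        make_attack("c3", "u3", "2020-01-08 07:00", "2020-01-08 08:00", 2,
                    aura=True),
    ]
    medications = [
        MedicationIntake("u1", "Sumatriptan", "50 mg",
                         datetime.fromisoformat("2020-01-02 08:30")),
        MedicationIntake("u1", "ibuprofen", "400 mg",
                         datetime.fromisoformat("2020-01-20 12:00")),
        MedicationIntake("u2", "ibuprofen", "400 mg",
                         datetime.fromisoformat("2020-01-03 10:00")),
    ]
    collection = DiaryCollection(users=users, attacks=attacks,
                                 medications=medications)
    fill_no_headache_entries(collection, n_days=4 * 28)
    return collection


#: (user_id, month) -> (mhd, mmd, amd, mean_hi, mean_mi); hand-counted.
HAND_EXPECTED = {
    ("u1", 1): (4, 3, 2, 5.0, 17 / 3),
    ("u1", 2): (2, 2, 0, 6.0, 6.0),
    ("u1", 3): (1, 1, 0, 6.0, 6.0),
    ("u1", 4): (1, 1, 0, 6.0, 6.0),
    ("u2", 1): (2, 0, 1, 3.0, None),
    ("u2", 2): (0, 0, 0, None, None),
    ("u2", 3): (0, 0, 0, None, None),
    ("u2", 4): (0, 0, 0, None, None),
    ("u3", 1): (2, 2, 0, 4.0, 4.0),
    ("u3", 2): (0, 0, 0, None, None),
    ("u3", 3): (0, 0, 0, None, None),
    ("u3", 4): (0, 0, 0, None, None),
}

#: per-attack hand classification
HAND_LABELS = {
    "a1": "MIGRAINE", "a2": "MIGRAINE", "a3": "TTH", "f1": "MIGRAINE",
    "f2": "MIGRAINE", "f3": "MIGRAINE", "a4": "MIGRAINE",
    "b1": "TTH", "b2": "TTH", "c1": "MIGRAINE", "c3": "MIGRAINE",
}

HAND_GROUPS = {"u1": "EPISODIC_MIGRAINE", "u2": "OTHER", "u3": "OTHER"}

#: baseline (month 1) vs month 4 paired t on MHD over [u1, u2, u3]:
#: d = [3, 2, 2]; mean 7/3, t = 7.0, df = 2, p = 0.01980393,
#: CI = 7/3 +- 4.30265273 / 3
HAND_T_MHD = dict(mean_diff=7 / 3, t_stat=7.0, df=2, p_value=0.0198039412,
                  ci_low=0.8991158, ci_high=3.7675509)


@pytest.fixture
def hand_fixture() -> DiaryCollection:
    return build_hand_fixture()


@pytest.fixture
def simple_collection() -> DiaryCollection:
    u = UserProfile("u1", Sex.FEMALE, 30, PriorDiagnosis.MIGRAINE,
                    date(2020, 1, 1))
    return DiaryCollection(users=[u], attacks=[make_attack()])
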