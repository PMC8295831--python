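"""Rule engine labelling single attacks as migraine, TTH, or other.

The decision procedure, in order:

1. *Override*: aura, or an attributable migraine-specific intake, forces
   MIGRAINE regardless of duration and pain features.
2. *Qualified migraine*: duration >= 4 h AND feature A (>= 2 of unilateral,
   throbbing, moderate-or-severe intensity, aggravation by activity) AND
   feature B (nausea, or vomiting, or photophobia together with
   phonophobia).
3. Attacks fulfilling both TTH and probable-migraine criteria are counted
   as migraine for users with a prior migraine diagnosis and as TTH
   otherwise (general rule of hierarchy).
4. TTH alone -> TTH; probable migraine alone -> MIGRAINE only under a
   prior migraine diagnosis, else OTHER; anything left -> OTHER.

Probable migraine is operationalized as "exactly one of the three
qualified-migraine conjuncts fails"; the TTH criteria follow ICHD-3
chapter 2 (duration 30 min - 168 h, >= 2 negated pain features, no
nausea/vomiting, at most one of photophobia/phonophobia).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .model import DiaryCollection, HeadacheAttack, MedicationIntake, PriorDiagnosis

DEFAULT_MIGRAINE_SPECIFIC_DRUGS = (
    "sumatriptan", "zolmitriptan", "rizatriptan", "eletriptan",
    "almotriptan", "naratriptan", "frovatriptan",
)


class HeadacheLabel(str, Enum):
    MIGRAINE = "MIGRAINE"
    TTH = "TTH"
    OTHER = "OTHER"


@dataclass(frozen=True)
class IntensityBands:
    """Cut points partitioning the 1-10 NRS into mild/moderate/severe.

    ``mild_max`` and ``moderate_max`` are inclusive upper bounds; 0 means
    no pain.  Defaults: mild 1-3, moderate 4-7, severe 8-10.
    """

    mild_max: int = 3
    moderate_max: int = 7

    def __post_init__(self):
        if not 1 <= self.mild_max < self.moderate_max <= 10:
            raise ValueError(
                f"bands must satisfy 1 <= mild_max < moderate_max <= 10, "
                f"got mild_max={self.mild_max}, moderate_max={self.moderate_max}")

    @property
    def moderate_min(self) -> int:
        return self.mild_max + 1


@dataclass(frozen=True)
class ClassifierConfig:
    bands: IntensityBands = field(default_factory=IntensityBands)
    migraine_min_duration_h: float = 4.0
    tth_min_duration_h: float = 0.5
    tth_max_duration_h: float = 168.0
    migraine_specific_drugs: tuple[str, ...] = DEFAULT_MIGRAINE_SPECIFIC_DRUGS
    attribution_window_h: float = 1.0


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(slots=True)
class AttackClassification:
    attack_id: str
    label: HeadacheLabel
    rule_trace: list[str]


def attack_duration_hours(attack: HeadacheAttack) -> float:
    """Attack duration in hours, exact to the second."""
    return (attack.end - attack.start).total_seconds() / 3600.0


def meets_feature_A(attack: HeadacheAttack,
                    bands: IntensityBands = IntensityBands()) -> bool:
    """>= 2 of: unilateral, throbbing, moderate-or-severe intensity,
    aggravation by physical activity."""
    indicators = (
        attack.unilateral,
        attack.throbbing,
        attack.max_intensity >= bands.moderate_min,
        attack.worse_with_activity,
    )
    return sum(indicators) >= 2


def meets_feature_B(attack: HeadacheAttack) -> bool:
    """Nausea, or vomiting, or photophobia AND phonophobia."""
    return attack.nausea or attack.vomitus or (
        attack.photophobia and attack.phonophobia)


def is_qualified_migraine(attack: HeadacheAttack,
                          config: ClassifierConfig = DEFAULT_CONFIG) -> bool:
    return (attack_duration_hours(attack) >= config.migraine_min_duration_h
            and meets_feature_A(attack, config.bands)
            and meets_feature_B(attack))


def is_migraine_specific(drug_name: str,
                         explicit_flag: Optional[bool] = None,
                         drug_list: Sequence[str] = DEFAULT_MIGRAINE_SPECIFIC_DRUGS
                         ) -> bool:
    """Whether a recorded intake counts as migraine-specific medication.

    An explicit flag takes precedence; otherwise a case-insensitive
    substring match against the configured acute-migraine drug list
    (triptans by default) is used.
    """
    if explicit_flag is not None:
        return explicit_flag
    name = drug_name.lower()
    return any(d.lower() in name for d in drug_list)


def has_migraine_override(attack: HeadacheAttack,
                          meds: Sequence[MedicationIntake],
                          config: ClassifierConfig = DEFAULT_CONFIG) -> bool:
    """Aura or an attributable migraine-specific intake forces migraine.

    ``meds`` must already be restricted to intakes attributable to this
    attack (see :func:`attribute_medications`).
    """
    if attack.aura:
        return True
    return any(is_migraine_specific(m.drug_name, m.migraine_specific,
                                    config.migraine_specific_drugs)
               for m in meds)


def meets_tth_criteria(attack: HeadacheAttack,
                       config: ClassifierConfig = DEFAULT_CONFIG) -> bool:
    dur = attack_duration_hours(attack)
    if not config.tth_min_duration_h <= dur <= config.tth_max_duration_h:
        return False
    negated = (
        not attack.unilateral,
        not attack.throbbing,
        attack.max_intensity <= config.bands.moderate_max,
        not attack.worse_with_activity,
    )
    if sum(negated) < 2:
        return False
    if attack.nausea or attack.vomitus:
        return False
    return int(attack.photophobia) + int(attack.phonophobia) <= 1


def meets_probable_migraine(attack: HeadacheAttack,
                            config: ClassifierConfig = DEFAULT_CONFIG) -> bool:
    """Exactly one of {duration >= 4 h, feature A, feature B} fails."""
    failures = (
        int(attack_duration_hours(attack) < config.migraine_min_duration_h)
        + int(not meets_feature_A(attack, config.bands))
        + int(not meets_feature_B(attack))
    )
    return failures == 1


def classify_attack(attack: HeadacheAttack,
                    meds: Sequence[MedicationIntake],
                    prior_diagnosis: PriorDiagnosis = PriorDiagnosis.UNKNOWN,
                    config: ClassifierConfig = DEFAULT_CONFIG
                    ) -> AttackClassification:
    """Label one attack; ``meds`` are the intakes attributable to it."""
    trace: list[str] = []
    prior_migraine = prior_diagnosis is PriorDiagnosis.MIGRAINE

    if attack.aura:
        trace.append("override:aura")
    elif has_migraine_override(attack, meds, config):
        trace.append("override:migraine_specific_medication")
    if trace:
        return AttackClassification(attack.attack_id, HeadacheLabel.MIGRAINE,
                                    trace)

    if is_qualified_migraine(attack, config):
        return AttackClassification(attack.attack_id, HeadacheLabel.MIGRAINE,
                                    ["qualified_migraine"])

    tth = meets_tth_criteria(attack, config)
    probable = meets_probable_migraine(attack, config)

    if tth and probable:
        trace += ["tth", "probable_migraine"]
        if prior_migraine:
            trace.append("hierarchy:prior_migraine_diagnosis")
            return AttackClassification(attack.attack_id,
                                        HeadacheLabel.MIGRAINE, trace)
        trace.append("hierarchy:general_rule")
        return AttackClassification(attack.attack_id, HeadacheLabel.TTH, trace)
    if tth:
        return AttackClassification(attack.attack_id, HeadacheLabel.TTH,
                                    ["tth"])
    if probable and prior_migraine:
        return AttackClassification(
            attack.attack_id, HeadacheLabel.MIGRAINE,
            ["probable_migraine", "prior_migraine_diagnosis"])
    if probable:
        return AttackClassification(attack.attack_id, HeadacheLabel.OTHER,
                                    ["probable_migraine", "no_prior_diagnosis"])
    return AttackClassification(attack.attack_id, HeadacheLabel.OTHER,
                                ["unclassified"])


def attribute_medications(attacks: Sequence[HeadacheAttack],
                          medications: Sequence[MedicationIntake],
                          config: ClassifierConfig = DEFAULT_CONFIG
                          ) -> dict[str, list[MedicationIntake]]:
    """Temporal join: intake belongs to an attack iff its time lies in
    ``[start - attribution_window, end]``.  Returns attack_id -> intakes."""
    from datetime import timedelta

    window = timedelta(hours=config.attribution_window_h)
    by_user: dict[str, list[MedicationIntake]] = {}
    for m in medications:
        by_user.setdefault(m.user_id, []).append(m)
    times_by_user: dict[str, list] = {}
    for uid, meds in by_user.items():
        meds.sort(key=lambda m: m.intake_time)
        times_by_user[uid] = [m.intake_time for m in meds]

    result: dict[str, list[MedicationIntake]] = {}
    for a in attacks:
        meds = by_user.get(a.user_id, [])
        times = times_by_user.get(a.user_id, [])
        lo = bisect.bisect_left(times, a.start - window)
        hi = bisect.bisect_right(times, a.end)
        result[a.attack_id] = meds[lo:hi]
    return result


def classify_collection(collection: DiaryCollection,
                        config: ClassifierConfig = DEFAULT_CONFIG
                        ) -> list[AttackClassification]:
    """Classify every attack of a diary collection."""
    users = collection.user_map()
    attributed = attribute_medications(collection.attacks,
                                       collection.medications, config)
    out = []
    for a in collection.attacks:
        dx = users[a.user_id].prior_diagnosis
        out.append(classify_attack(a, attributed[a.attack_id], dx, config))
    return out
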