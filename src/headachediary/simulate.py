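"""Synthetic diary cohorts with known ground truth.

Each user carries a latent type (migraine-like or tension-like symptom
profile) and a per-day attack hazard that declines multiplicatively per
28-day month:  h(u, m) = baseline_daily_hazard * monthly_decline**(m-1).
Days are independent Bernoulli draws; by default each attack is confined
to its calendar day, so a user's monthly headache-day count is exactly
Binomial(28, h(u, m)) and closed-form expectations are available for
testing (:func:`expected_mhd`).  Every attack-free day receives a
``no_headache`` entry, so generated users always satisfy the daily-use
cohort rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .aggregate import DAYS_PER_MONTH
from .model import (
    DailyEntry,
    DiaryCollection,
    EntryKind,
    HeadacheAttack,
    MedicationIntake,
    PriorDiagnosis,
    Sex,
    UserProfile,
)

MIGRAINEUR = "migraineur"
TTH_TYPE = "tth_type"


class SymptomProfile(BaseModel):
    """Per-attack symptom probabilities and intensity distribution for one
    latent attack type."""

    model_config = ConfigDict(extra="forbid")

    unilateral: float = Field(ge=0, le=1)
    throbbing: float = Field(ge=0, le=1)
    worse_with_activity: float = Field(ge=0, le=1)
    nausea: float = Field(ge=0, le=1)
    vomitus: float = Field(ge=0, le=1)
    photophobia: float = Field(ge=0, le=1)
    phonophobia: float = Field(ge=0, le=1)
    aura: float = Field(ge=0, le=1)
    intensity_weights: list[float] = Field(min_length=11, max_length=11)
    duration_median_h: float = Field(gt=0)
    duration_sigma: float = Field(default=0.4, ge=0)

    @model_validator(mode="after")
    def _check_weights(self):
        if any(w < 0 for w in self.intensity_weights):
            raise ValueError("intensity_weights must be nonnegative")
        if sum(self.intensity_weights) <= 0:
            raise ValueError("intensity_weights must sum to > 0")
        return self


def _default_migraine_profile() -> SymptomProfile:
    # chosen so that (with a prior migraine diagnosis) >= 95% of
    # migraineur-type attacks classify as MIGRAINE
    return SymptomProfile(
        unilateral=0.7, throbbing=0.8, worse_with_activity=0.6,
        nausea=0.6, vomitus=0.2, photophobia=0.7, phonophobia=0.6, aura=0.2,
        intensity_weights=[0, 0, 0, 0.05, 0.1, 0.2, 0.3, 0.2, 0.1, 0.04, 0.01],
        duration_median_h=12.0)


def _default_tth_profile() -> SymptomProfile:
    return SymptomProfile(
        unilateral=0.1, throbbing=0.1, worse_with_activity=0.1,
        nausea=0.0, vomitus=0.0, photophobia=0.15, phonophobia=0.15, aura=0.0,
        intensity_weights=[0, 0.05, 0.2, 0.3, 0.25, 0.15, 0.05, 0, 0, 0, 0],
        duration_median_h=4.0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_users: int = Field(ge=1)
    months: int = Field(default=7, ge=1)
    frac_migraineur: float = Field(default=0.7, ge=0, le=1)
    baseline_daily_hazard: float = Field(ge=0, lt=1)
    monthly_decline: float = Field(default=1.0, ge=0, le=1)
    migraine_profile: SymptomProfile = Field(
        default_factory=_default_migraine_profile)
    tth_profile: SymptomProfile = Field(default_factory=_default_tth_profile)
    p_acute_medication: float = Field(default=0.5, ge=0, le=1)
    p_triptan_given_migraineur: float = Field(default=0.5, ge=0, le=1)
    p_female: float = Field(default=0.85, ge=0, le=1)
    p_missing_sex: float = Field(default=0.3, ge=0, le=1)
    p_missing_age: float = Field(default=0.25, ge=0, le=1)
    prior_dx_rule: Literal["by_type", "none", "unknown"] = "by_type"
    frac_high_frequency: float = Field(default=0.0, ge=0, le=1)
    high_frequency_hazard: float = Field(default=0.6, gt=0, lt=1)
    hazard_concentration: Optional[float] = Field(default=None, gt=0)
    allow_multiday: bool = False
    start_date: date = date(2019, 1, 1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_feasible(self):
        # back-to-back multi-day attacks cannot avoid overlap at extreme
        # hazards; single-day attacks are always feasible
        if self.allow_multiday and max(
                self.baseline_daily_hazard, self.high_frequency_hazard) > 0.9:
            raise ValueError("infeasible config: daily hazard > 0.9 with "
                             "multi-day attacks enabled")
        return self


@dataclass(slots=True)
class GroundTruth:
    """Latent state recorded alongside every generated collection."""
    user_type: dict[str, str] = field(default_factory=dict)
    high_frequency: dict[str, bool] = field(default_factory=dict)
    monthly_hazards: dict[str, list[float]] = field(default_factory=dict)
    attack_type: dict[str, str] = field(default_factory=dict)


def expected_mhd(config: SimulationConfig, month: int) -> float:
    """Closed-form expected monthly headache days for a given month
    (single-day attacks): 28 * E[h_user] * monthly_decline**(month-1)."""
    if month < 1:
        raise ValueError("month must be >= 1")
    h = ((1.0 - config.frac_high_frequency) * config.baseline_daily_hazard
         + config.frac_high_frequency * config.high_frequency_hazard)
    return DAYS_PER_MONTH * h * config.monthly_decline ** (month - 1)


def sample_mhd_matrix(config: SimulationConfig, n_reps: int = 1,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw monthly headache-day counts directly from the generative model.

    For single-day attacks the day process is Bernoulli(h(u, m)) per day,
    so MHD per user-month is exactly Binomial(28, h(u, m)); sampling the
    Binomial is an exact shortcut that skips diary construction.  Returns
    an array of shape (n_reps, n_users, months).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = _user_base_hazards(config, rng, (n_reps, config.n_users))
    decline = config.monthly_decline ** np.arange(config.months)
    h = base[..., None] * decline
    return rng.binomial(DAYS_PER_MONTH, h)


def _user_base_hazards(config: SimulationConfig, rng: np.random.Generator,
                       shape) -> np.ndarray:
    hf = rng.random(shape) < config.frac_high_frequency
    base = np.where(hf, config.high_frequency_hazard,
                    config.baseline_daily_hazard)
    if config.hazard_concentration is not None:
        nu = config.hazard_concentration
        base = rng.beta(base * nu, (1.0 - base) * nu)
        base = np.clip(base, 1e-9, 1.0 - 1e-9)
    return base


_TRIPTANS = ("sumatriptan", "rizatriptan", "zolmitriptan")
_ANALGESICS = ("ibuprofen", "paracetamol", "naproxen", "aspirin")
_FLAG_NAMES = ("unilateral", "throbbing", "worse_with_activity", "nausea",
               "vomitus", "photophobia", "phonophobia", "aura")


def generate_cohort(config: SimulationConfig
                    ) -> tuple[DiaryCollection, GroundTruth]:
    """Generate a fully adherent diary cohort plus its ground truth.

    Deterministic given ``config.seed``.  The returned collection passes
    full diary validation and every user satisfies the daily-use rule for
    ``config.months`` months.
    """
    rng = np.random.default_rng(config.seed)
    n_days = DAYS_PER_MONTH * config.months
    truth = GroundTruth()
    users, attacks, medications, entries = [], [], [], []

    is_migraineur = rng.random(config.n_users) < config.frac_migraineur
    hf_mask = rng.random(config.n_users) < config.frac_high_frequency
    sexes = rng.random(config.n_users)
    sex_missing = rng.random(config.n_users) < config.p_missing_sex
    ages = np.clip(np.rint(rng.normal(37.0, 11.0, config.n_users)),
                   18, 80).astype(int)
    age_missing = rng.random(config.n_users) < config.p_missing_age
    decline = config.monthly_decline ** np.arange(config.months)
    day_month = np.repeat(np.arange(config.months), DAYS_PER_MONTH)

    for i in range(config.n_users):
        uid = f"u{i:05d}"
        # high-frequency stratum users are always migraine-like, so they
        # can populate the chronic-migraine subgroup
        migraineur = bool(is_migraineur[i]) or bool(hf_mask[i])
        utype = MIGRAINEUR if migraineur else TTH_TYPE
        profile = (config.migraine_profile if migraineur
                   else config.tth_profile)

        base = (config.high_frequency_hazard if hf_mask[i]
                else config.baseline_daily_hazard)
        if config.hazard_concentration is not None:
            nu = config.hazard_concentration
            base = float(np.clip(rng.beta(base * nu, (1.0 - base) * nu),
                                 1e-9, 1.0 - 1e-9))
        hazards = base * decline
        truth.user_type[uid] = utype
        truth.high_frequency[uid] = bool(hf_mask[i])
        truth.monthly_hazards[uid] = [float(h) for h in hazards]

        if config.prior_dx_rule == "by_type":
            dx = PriorDiagnosis.MIGRAINE if migraineur else PriorDiagnosis.NONE
        elif config.prior_dx_rule == "none":
            dx = PriorDiagnosis.NONE
        else:
            dx = PriorDiagnosis.UNKNOWN
        users.append(UserProfile(
            user_id=uid,
            sex=(Sex.UNKNOWN if sex_missing[i]
                 else (Sex.FEMALE if sexes[i] < config.p_female else Sex.MALE)),
            age=None if age_missing[i] else int(ages[i]),
            prior_diagnosis=dx,
            first_use_date=config.start_date,
        ))

        attack_days = np.nonzero(rng.random(n_days)
                                 < hazards[day_month])[0]
        k = attack_days.size
        if k:
            durations = np.exp(rng.normal(np.log(profile.duration_median_h),
                                          profile.duration_sigma, k))
            flags = {name: rng.random(k) < getattr(profile, name)
                     for name in _FLAG_NAMES}
            weights = np.asarray(profile.intensity_weights, dtype=float)
            intensities = rng.choice(11, size=k, p=weights / weights.sum())
            med_mask = rng.random(k) < config.p_acute_medication
            triptan_mask = (med_mask & migraineur
                            & (rng.random(k) < config.p_triptan_given_migraineur))
            drug_pick = rng.integers(0, 4, k)

            covered: list[int] = []
            prev_end: Optional[datetime] = None
            for j, day_off in enumerate(attack_days):
                day = config.start_date + timedelta(days=int(day_off))
                if config.allow_multiday:
                    dur = float(np.clip(durations[j], 0.5, 72.0))
                    start_h = rng.uniform(0.0, 23.0)
                else:
                    dur = float(np.clip(durations[j], 0.5, 23.5))
                    start_h = rng.uniform(0.0, 24.0 - dur)
                start = datetime.combine(day, time.min) + timedelta(
                    minutes=round(start_h * 60))
                end = start + timedelta(minutes=round(dur * 60))
                if not config.allow_multiday:
                    # keep the attack strictly within its calendar day
                    day_last = datetime.combine(day, time.min) + timedelta(
                        minutes=24 * 60 - 1)
                    end = min(end, day_last)
                if prev_end is not None and start <= prev_end:
                    start = prev_end + timedelta(minutes=1)
                if end <= start:
                    end = start + timedelta(minutes=30)
                if config.allow_multiday and j + 1 < k:
                    next_day = datetime.combine(
                        config.start_date
                        + timedelta(days=int(attack_days[j + 1])), time.min)
                    if end >= next_day:
                        end = next_day - timedelta(minutes=1)
                last_day = min((end.date() - config.start_date).days,
                               n_days - 1)
                covered.extend(range(int(day_off), last_day + 1))
                prev_end = end

                aid = f"a{i:05d}_{j:04d}"
                attacks.append(HeadacheAttack(
                    attack_id=aid, user_id=uid, start=start, end=end,
                    max_intensity=int(intensities[j]),
                    **{name: bool(flags[name][j]) for name in _FLAG_NAMES}))
                truth.attack_type[aid] = utype

                if med_mask[j]:
                    if triptan_mask[j]:
                        drug = _TRIPTANS[drug_pick[j] % len(_TRIPTANS)]
                        dose = "50 mg"
                    else:
                        drug = _ANALGESICS[drug_pick[j]]
                        dose = "400 mg"
                    medications.append(MedicationIntake(
                        user_id=uid, drug_name=drug, dose=dose,
                        intake_time=start + timedelta(minutes=15),
                        migraine_specific=None))
            covered_set = frozenset(covered)
        else:
            covered_set = frozenset()

        entries.extend(
            DailyEntry(uid, config.start_date + timedelta(days=d),
                       EntryKind.NO_HEADACHE)
            for d in range(n_days) if d not in covered_set)

    return (DiaryCollection(users=users, attacks=attacks,
                            medications=medications, entries=entries),
            truth)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """TSV: user_id, latent type, high-frequency flag, per-month hazards."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("user_id\tuser_type\thigh_frequency\tmonthly_hazards\n")
        for uid, utype in truth.user_type.items():
            hz = ",".join(f"{h:.6g}" for h in truth.monthly_hazards[uid])
            fh.write(f"{uid}\t{utype}\t"
                     f"{str(truth.high_frequency[uid]).lower()}\t{hz}\n")
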