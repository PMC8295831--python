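"""Cohort statistics: demographics, paired t tests, repeated-measures ANOVA.

Mean differences and confidence intervals are oriented as baseline minus
follow-up, so a decrease over time yields a positive difference.
Percentages in demographic summaries always use available-data
denominators (missing values are excluded from the denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .aggregate import DiagnosisGroup, DiagnosisLabel, MonthlyOutcome
from .model import Sex, UserProfile


@dataclass(slots=True)
class PairedTestResult:
    outcome_name: str
    n: int
    baseline_mean: float
    baseline_sd: float
    followup_mean: float
    followup_sd: float
    mean_diff: float          # baseline - follow-up
    t_stat: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(slots=True)
class AnovaResult:
    outcome_name: str
    n_subjects: int
    k_timepoints: int
    f_stat: float
    df_time: int
    df_error: int
    p_value: float


@dataclass(slots=True)
class DemographicsSummary:
    subgroup: str
    n_total: int
    n_female: int
    pct_female: Optional[float]   # over non-missing sex; None if none known
    n_missing_sex: int
    mean_age: Optional[float]
    sd_age: Optional[float]
    n_missing_age: int


@dataclass(slots=True)
class OutcomeTableRow:
    """One outcome x subgroup comparison; ``result`` is None when the cell
    is not computable (fewer than 2 complete pairs or zero variance)."""
    outcome_name: str
    subgroup: str
    result: Optional[PairedTestResult]
    note: Optional[str] = None


def paired_t_test(baseline: Sequence[float], followup: Sequence[float],
                  alpha: float = 0.05,
                  outcome_name: str = "") -> PairedTestResult:
    """Classical paired-samples t test on d = baseline - followup.

    Two-tailed p; (1 - alpha) CI of the mean difference.  Raises
    ValueError for n < 2, length mismatch, or zero variance of the
    differences.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.ndim != 1:
        raise ValueError(f"length mismatch: {b.shape} vs {f.shape}")
    n = b.size
    if n < 2:
        raise ValueError(f"n < 2 (got n={n})")
    d = b - f
    sd_d = d.std(ddof=1)
    if sd_d == 0.0:
        raise ValueError("degenerate: zero variance")
    mean_d = d.mean()
    se = sd_d / math.sqrt(n)
    t_stat = mean_d / se
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t_stat), df)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return PairedTestResult(
        outcome_name=outcome_name, n=n,
        baseline_mean=float(b.mean()), baseline_sd=float(b.std(ddof=1)),
        followup_mean=float(f.mean()), followup_sd=float(f.std(ddof=1)),
        mean_diff=float(mean_d), t_stat=float(t_stat), df=df,
        p_value=float(p),
        ci_low=float(mean_d - t_crit * se),
        ci_high=float(mean_d + t_crit * se),
    )


def repeated_measures_anova(matrix, outcome_name: str = "") -> AnovaResult:
    """One-way within-subjects ANOVA on a complete subjects x timepoints
    matrix: F = MS_time / MS_error with the subject effect removed."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x timepoints)")
    if np.isnan(x).any():
        raise ValueError("incomplete matrix: listwise completeness required")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 timepoints, got {x.shape}")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_time = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_error = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0.0:
        raise ValueError("degenerate: zero variance")
    f_stat = (ss_time / df_time) / ms_error
    p = float(sps.f.sf(f_stat, df_time, df_error))
    return AnovaResult(outcome_name=outcome_name, n_subjects=n,
                       k_timepoints=k, f_stat=float(f_stat),
                       df_time=df_time, df_error=df_error, p_value=p)


def summarize_demographics(users: Sequence[UserProfile],
                           groups: Optional[Sequence[DiagnosisGroup]] = None
                           ) -> dict[str, DemographicsSummary]:
    """Demographic summaries for "all" plus each diagnosis subgroup.

    pct_female uses only users with non-missing sex; mean/SD age only
    users with non-missing age.
    """
    group_of = {g.user_id: g.group for g in (groups or [])}
    subsets: dict[str, list[UserProfile]] = {"all": list(users)}
    if groups is not None:
        for label in (DiagnosisLabel.EPISODIC_MIGRAINE,
                      DiagnosisLabel.CHRONIC_MIGRAINE, DiagnosisLabel.OTHER):
            subsets[label.lower()] = [u for u in users
                                      if group_of.get(u.user_id) == label]
    out = {}
    for name, subset in subsets.items():
        n_total = len(subset)
        n_missing_sex = sum(1 for u in subset if u.sex is Sex.UNKNOWN)
        n_female = sum(1 for u in subset if u.sex is Sex.FEMALE)
        n_known = n_total - n_missing_sex
        ages = [u.age for u in subset if u.age is not None]
        out[name] = DemographicsSummary(
            subgroup=name,
            n_total=n_total,
            n_female=n_female,
            pct_female=100.0 * n_female / n_known if n_known else None,
            n_missing_sex=n_missing_sex,
            mean_age=float(np.mean(ages)) if ages else None,
            sd_age=float(np.std(ages, ddof=1)) if len(ages) > 1 else None,
            n_missing_age=n_total - len(ages),
        )
    return out


OUTCOME_COLUMNS = ("mhd", "mmd", "amd",
                   "mean_headache_intensity", "mean_migraine_intensity")
_INTENSITY_OUTCOMES = frozenset({"mean_headache_intensity",
                                 "mean_migraine_intensity"})


def build_outcome_table(outcomes: Sequence[MonthlyOutcome],
                        groups: Optional[Sequence[DiagnosisGroup]],
                        baseline_month: int, followup_month: int,
                        alpha: float = 0.05) -> list[OutcomeTableRow]:
    """Baseline-vs-follow-up paired t test per outcome x subgroup.

    Count outcomes use every user with both months present; intensity
    outcomes additionally require the intensity to be defined (>= 1
    qualifying day) in both months.
    """
    by_user_month: dict[tuple[str, int], MonthlyOutcome] = {
        (o.user_id, o.month_index): o for o in outcomes}
    user_ids = sorted({o.user_id for o in outcomes})
    group_of = {g.user_id: g.group for g in (groups or [])}

    subgroups: dict[str, list[str]] = {"all": user_ids}
    if groups is not None:
        for label in (DiagnosisLabel.EPISODIC_MIGRAINE,
                      DiagnosisLabel.CHRONIC_MIGRAINE):
            subgroups[label.lower()] = [u for u in user_ids
                                        if group_of.get(u) == label]

    rows = []
    for sub_name, uids in subgroups.items():
        for outcome in OUTCOME_COLUMNS:
            base, fup = [], []
            for uid in uids:
                o_b = by_user_month.get((uid, baseline_month))
                o_f = by_user_month.get((uid, followup_month))
                if o_b is None or o_f is None:
                    continue
                vb = getattr(o_b, outcome)
                vf = getattr(o_f, outcome)
                if outcome in _INTENSITY_OUTCOMES and (vb is None or vf is None):
                    continue
                base.append(float(vb))
                fup.append(float(vf))
            try:
                result = paired_t_test(base, fup, alpha=alpha,
                                       outcome_name=outcome)
                rows.append(OutcomeTableRow(outcome, sub_name, result))
            except ValueError as exc:
                rows.append(OutcomeTableRow(outcome, sub_name, None,
                                            note=str(exc)))
    return rows
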