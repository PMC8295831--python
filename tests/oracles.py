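"""Independent brute-force oracles, written before the implementations
they check and kept deliberately flat and enumeration-style."""

from __future__ import annotations

from datetime import date, datetime, timedelta


def oracle_label(duration_h: float, unilateral: bool, throbbing: bool,
                 activity: bool, nausea: bool, vomitus: bool,
                 photophobia: bool, phonophobia: bool, aura: bool,
                 intensity: int, triptan: bool, prior_migraine: bool) -> str:
    """Flat truth-table classification of a single attack."""
    a_count = (int(unilateral) + int(throbbing) + int(intensity >= 4)
               + int(activity))
    feat_a = a_count >= 2
    feat_b = nausea or vomitus or (photophobia and phonophobia)
    qualified = duration_h >= 4.0 and feat_a and feat_b
    override = aura or triptan

    neg_count = (int(not unilateral) + int(not throbbing)
                 + int(intensity <= 7) + int(not activity))
    tth = (0.5 <= duration_h <= 168.0
           and neg_count >= 2
           and not nausea and not vomitus
           and int(photophobia) + int(phonophobia) <= 1)

    n_failed = (int(duration_h < 4.0) + int(not feat_a) + int(not feat_b))
    probable = n_failed == 1

    if override:
        return "MIGRAINE"
    if qualified:
        return "MIGRAINE"
    if tth and probable:
        return "MIGRAINE" if prior_migraine else "TTH"
    if tth:
        return "TTH"
    if probable and prior_migraine:
        return "MIGRAINE"
    return "OTHER"


def stepping_calendar_days(start: datetime, end: datetime,
                           step_minutes: int = 30) -> set[date]:
    """Calendar days touched by [start, end], by brute-force time stepping."""
    days = set()
    t = start
    step = timedelta(minutes=step_minutes)
    while t < end:
        days.add(t.date())
        t += step
    days.add(end.date())
    days.add(start.date())
    return days


def anova_f_by_loops(matrix) -> tuple[float, int, int]:
    """Within-subjects one-way ANOVA F via explicit sums-of-squares loops."""
    n = len(matrix)
    k = len(matrix[0])
    total = sum(sum(row) for row in matrix)
    grand = total / (n * k)

    time_means = [sum(matrix[s][t] for s in range(n)) / n for t in range(k)]
    subj_means = [sum(matrix[s]) / k for s in range(n)]

    ss_total = 0.0
    for s in range(n):
        for t in range(k):
            ss_total += (matrix[s][t] - grand) ** 2
    ss_time = sum(n * (tm - grand) ** 2 for tm in time_means)
    ss_subj = sum(k * (sm - grand) ** 2 for sm in subj_means)
    ss_error = ss_total - ss_time - ss_subj

    df_time = k - 1
    df_error = (k - 1) * (n - 1)
    f = (ss_time / df_time) / (ss_error / df_error)
    return f, df_time, df_error


def intervals_overlap(s1, e1, s2, e2) -> bool:
    """Half-open interval intersection test used as the overlap oracle."""
    return max(s1, s2) < min(e1, e2)
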