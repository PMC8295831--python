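from __future__ import annotations

import itertools
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headachediary.classifier import (
    AttackClassification,
    ClassifierConfig,
    HeadacheLabel,
    IntensityBands,
    attack_duration_hours,
    attribute_medications,
    classify_attack,
    has_migraine_override,
    is_migraine_specific,
    is_qualified_migraine,
    meets_feature_A,
    meets_feature_B,
    meets_probable_migraine,
    meets_tth_criteria,
)
from headachediary.model import MedicationIntake, PriorDiagnosis

from .conftest import make_attack
from .oracles import oracle_label

BANDS = IntensityBands()
CFG = ClassifierConfig()

FLAG_NAMES = ("unilateral", "throbbing", "worse_with_activity", "nausea",
              "vomitus", "photophobia", "phonophobia", "aura")


def attack_from_grid(duration_h, intensity, flag_bits):
    start = datetime(2020, 1, 5, 8, 0)
    flags = dict(zip(FLAG_NAMES, flag_bits))
    return make_attack(start="2020-01-05 08:00",
                       end=(start + timedelta(hours=duration_h)).isoformat(),
                       max_intensity=intensity, **flags)


def triptan_intake(attack):
    return MedicationIntake(attack.user_id, "sumatriptan", "50 mg",
                            attack.start + timedelta(minutes=10))


class TestDuration:
    def test_four_hours(self):
        assert attack_duration_hours(make_attack()) == 4.0

    def test_overnight(self):
        a = make_attack(start="2020-01-05 23:00", end="2020-01-06 03:30")
        # minute-count oracle
        assert (a.end - a.start) // timedelta(minutes=1) == 270
        assert attack_duration_hours(a) == 4.5

    def test_half_hour(self):
        a = make_attack(end="2020-01-05 10:30")
        assert attack_duration_hours(a) == 0.5


class TestFeatureA:
    def test_two_pain_features_suffice(self):
        a = make_attack(unilateral=True, throbbing=True, max_intensity=3)
        assert meets_feature_A(a, BANDS)

    def test_all_negative(self):
        assert not meets_feature_A(make_attack(max_intensity=2), BANDS)

    def test_intensity_plus_activity(self):
        a = make_attack(max_intensity=9, worse_with_activity=True)
        assert meets_feature_A(a, BANDS)

    def test_count_of_four_oracle_grid(self):
        for uni, throb, act in itertools.product([False, True], repeat=3):
            for intensity in range(11):
                a = make_attack(unilateral=uni, throbbing=throb,
                                worse_with_activity=act,
                                max_intensity=intensity)
                expected = (uni + throb + act + (intensity >= 4)) >= 2
                assert meets_feature_A(a, BANDS) == expected


class TestFeatureB:
    def test_nausea_alone(self):
        assert meets_feature_B(make_attack(nausea=True))

    def test_photophobia_alone_insufficient(self):
        assert not meets_feature_B(make_attack(photophobia=True))

    def test_photo_and_phono(self):
        assert meets_feature_B(make_attack(photophobia=True,
                                           phonophobia=True))

    def test_all_false(self):
        assert not meets_feature_B(make_attack())


class TestQualifiedMigraine:
    def test_qualified(self):
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True, nausea=True)
        assert is_qualified_migraine(a, CFG)

    def test_duration_boundary(self):
        a = make_attack(end="2020-01-05 13:54", unilateral=True,
                        throbbing=True, nausea=True)  # 3.9 h
        assert not is_qualified_migraine(a, CFG)

    def test_feature_a_only(self):
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True)
        assert not is_qualified_migraine(a, CFG)


class TestOverride:
    def test_aura_short_attack(self):
        a = make_attack(end="2020-01-05 11:00", aura=True)
        assert has_migraine_override(a, [], CFG)

    def test_triptan_during_attack(self):
        a = make_attack()
        assert has_migraine_override(a, [triptan_intake(a)], CFG)

    def test_ibuprofen_only(self):
        a = make_attack()
        m = MedicationIntake("u1", "ibuprofen", "400 mg",
                             a.start + timedelta(minutes=10))
        assert not has_migraine_override(a, [m], CFG)


class TestTth:
    def test_typical_tth(self):
        a = make_attack(end="2020-01-05 16:00", max_intensity=4)
        assert meets_tth_criteria(a, CFG)
        assert oracle_label(6, False, False, False, False, False, False,
                            False, False, 4, False, False) == "TTH"

    def test_nausea_excludes(self):
        a = make_attack(end="2020-01-05 16:00", max_intensity=4, nausea=True)
        assert not meets_tth_criteria(a, CFG)

    def test_both_photo_phono_excludes(self):
        a = make_attack(end="2020-01-05 16:00", max_intensity=4,
                        photophobia=True, phonophobia=True)
        assert not meets_tth_criteria(a, CFG)

    def test_too_short(self):
        a = make_attack(end="2020-01-05 10:15")
        assert not meets_tth_criteria(a, CFG)


class TestProbableMigraine:
    def test_one_failure(self):
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True)  # B fails only
        assert meets_probable_migraine(a, CFG)

    def test_qualified_is_not_probable(self):
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True, nausea=True)
        assert not meets_probable_migraine(a, CFG)

    def test_two_failures(self):
        a = make_attack(end="2020-01-05 12:00")  # 2 h, A fails, B fails
        assert not meets_probable_migraine(a, CFG)


class TestClassifyExamples:
    def test_qualified_migraine(self):
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True, nausea=True)
        c = classify_attack(a, [], PriorDiagnosis.NONE, CFG)
        assert c.label is HeadacheLabel.MIGRAINE
        assert c.rule_trace == ["qualified_migraine"]

    def test_hierarchy_general_rule(self):
        # TTH + probable migraine, no prior diagnosis -> TTH
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True, max_intensity=5)
        c = classify_attack(a, [], PriorDiagnosis.NONE, CFG)
        assert c.label is HeadacheLabel.TTH
        assert "hierarchy:general_rule" in c.rule_trace

    def test_hierarchy_prior_migraine(self):
        a = make_attack(end="2020-01-05 15:00", unilateral=True,
                        throbbing=True, max_intensity=5)
        c = classify_attack(a, [], PriorDiagnosis.MIGRAINE, CFG)
        assert c.label is HeadacheLabel.MIGRAINE
        assert "hierarchy:prior_migraine_diagnosis" in c.rule_trace

    def test_trace_nonempty_and_deterministic(self):
        a = make_attack(nausea=True, max_intensity=9)
        c1 = classify_attack(a, [], PriorDiagnosis.UNKNOWN, CFG)
        c2 = classify_attack(a, [], PriorDiagnosis.UNKNOWN, CFG)
        assert c1 == c2
        assert c1.rule_trace


GRID_DURATIONS = (0.5, 3, 4, 5, 80)
GRID_INTENSITIES = (2, 5, 9)


def full_grid():
    for bits in itertools.product([False, True], repeat=8):
        for dur in GRID_DURATIONS:
            for intensity in GRID_INTENSITIES:
                for triptan in (False, True):
                    for prior in (PriorDiagnosis.MIGRAINE,
                                  PriorDiagnosis.NONE):
                        yield bits, dur, intensity, triptan, prior


def test_full_factorial_grid_matches_oracle():
    """~15k-cell brute-force truth-table equivalence."""
    n = 0
    for bits, dur, intensity, triptan, prior in full_grid():
        a = attack_from_grid(dur, intensity, bits)
        meds = [triptan_intake(a)] if triptan else []
        got = classify_attack(a, meds, prior, CFG).label.value
        want = oracle_label(dur, *bits, intensity, triptan,
                            prior is PriorDiagnosis.MIGRAINE)
        assert got == want, (bits, dur, intensity, triptan, prior)
        n += 1
    assert n == 2 ** 8 * 5 * 3 * 2 * 2


def test_hierarchy_asymmetry():
    """prior_diagnosis changes the label only where probable migraine holds
    without qualified migraine or an override."""
    for bits, dur, intensity, triptan, prior in full_grid():
        if prior is not PriorDiagnosis.NONE:
            continue
        a = attack_from_grid(dur, intensity, bits)
        meds = [triptan_intake(a)] if triptan else []
        l_none = classify_attack(a, meds, PriorDiagnosis.NONE, CFG).label
        l_mig = classify_attack(a, meds, PriorDiagnosis.MIGRAINE, CFG).label
        if l_none != l_mig:
            assert meets_probable_migraine(a, CFG)
            assert not is_qualified_migraine(a, CFG)
            assert not has_migraine_override(a, meds, CFG)


attack_strategy = st.builds(
    attack_from_grid,
    duration_h=st.floats(min_value=0.1, max_value=200),
    intensity=st.integers(min_value=0, max_value=10),
    flag_bits=st.tuples(*[st.booleans()] * 8),
)


@settings(max_examples=200, deadline=None)
@given(attack=attack_strategy,
       prior=st.sampled_from(list(PriorDiagnosis)))
def test_override_dominance(attack, prior):
    """Adding aura or a migraine-specific intake always yields MIGRAINE."""
    with_aura = make_attack(start=attack.start.isoformat(),
                            end=attack.end.isoformat(),
                            max_intensity=attack.max_intensity,
                            **{f: getattr(attack, f) for f in FLAG_NAMES
                               if f != "aura"}, aura=True)
    assert classify_attack(with_aura, [], prior, CFG).label \
        is HeadacheLabel.MIGRAINE
    assert classify_attack(attack, [triptan_intake(attack)], prior,
                           CFG).label is HeadacheLabel.MIGRAINE


@settings(max_examples=200, deadline=None)
@given(attack=attack_strategy, extra=st.sampled_from(
    ["unilateral", "throbbing", "worse_with_activity", "nausea", "vomitus",
     "duration", "photo_phono"]))
def test_qualified_migraine_monotonic(attack, extra):
    """Adding indicators or lengthening duration never un-qualifies."""
    if not is_qualified_migraine(attack, CFG):
        return
    kwargs = {f: getattr(attack, f) for f in FLAG_NAMES}
    end = attack.end
    if extra == "duration":
        end = end + timedelta(hours=5)
    elif extra == "photo_phono":
        kwargs["photophobia"] = kwargs["phonophobia"] = True
    else:
        kwargs[extra] = True
    stronger = make_attack(start=attack.start.isoformat(),
                           end=end.isoformat(),
                           max_intensity=attack.max_intensity, **kwargs)
    assert is_qualified_migraine(stronger, CFG)


class TestMigraineSpecific:
    @pytest.mark.parametrize("name,expected", [
        ("Sumatriptan 50mg", True),
        ("ibuprofen", False),
        ("ZOLMITRIPTAN", True),
        ("naproxen 500 mg", False),
    ])
    def test_name_matching(self, name, expected):
        assert is_migraine_specific(name) is expected

    def test_explicit_flag_precedence(self):
        assert is_migraine_specific("unknown", explicit_flag=True) is True
        assert is_migraine_specific("sumatriptan", explicit_flag=False) is False


class TestAttribution:
    def test_window(self):
        a = make_attack()  # 10:00 - 14:00
        mk = lambda t: MedicationIntake("u1", "sumatriptan", "", t)
        before = mk(a.start - timedelta(hours=2))
        edge = mk(a.start - timedelta(minutes=59))
        during = mk(a.start + timedelta(hours=1))
        after = mk(a.end + timedelta(minutes=1))
        att = attribute_medications([a], [before, edge, during, after], CFG)
        assert att[a.attack_id] == [edge, during]

    def test_intensity_zero_with_flags_classifies_normally(self):
        a = make_attack(end="2020-01-05 15:00", max_intensity=0,
                        unilateral=True, throbbing=True, nausea=True)
        # intensity indicator false, but 2 of 4 still meet feature A
        assert classify_attack(a, [], PriorDiagnosis.NONE, CFG).label \
            is HeadacheLabel.MIGRAINE
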