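"""Program grid, eligibility, schedules, and the screening overlay."""

import dataclasses

import numpy as np
import pytest

from ctscreen import (Person, SmokingHistory, default_variants,
                      generate_cohort, is_eligible, parse_label,
                      format_label, program_grid, schedule_screens,
                      apply_screening, operative_candidacy_filter,
                      simulate_disease)
from ctscreen.params import CtSensitivity
from ctscreen.screening import (NLST_PROGRAM, Program, prepare_overlay,
                                run_scenario)
from ctscreen.natural_history import simulate_disease_cohort

from conftest import make_cohort


def always_eligible_person(oc=100.0):
    # heavy lifelong smoker: high pack-years at every screening age, YSQ 0
    return Person(sex=0, oc_death_age=oc,
                  smoking=SmokingHistory(init_age=16, intensity=40.0))


class TestProgramGrid:
    def test_grid_counts(self):
        programs, refs = program_grid()
        assert len(programs) == 576
        assert len({p.label for p in programs}) == 576
        assert len(refs) == 2 and len(programs) + len(refs) == 578

    def test_parse_example(self):
        p = parse_label("B55-85-20-15")
        assert (p.frequency, p.start_age, p.stop_age) == (2, 55, 85)
        assert (p.min_pack_years, p.max_ysq) == (20.0, 15.0)

    def test_labels_round_trip(self):
        programs, _ = program_grid()
        for p in programs:
            assert format_label(parse_label(p.label)) == p.label

    def test_invalid_labels_rejected(self):
        for bad in ("X55-85-20-15", "A55", "A85-55-20-15"):
            with pytest.raises(ValueError):
                parse_label(bad)

    def test_nlst_reference_arm(self):
        assert list(NLST_PROGRAM.candidate_ages()) == [62, 63, 64]
        assert NLST_PROGRAM.min_pack_years == 30
        assert NLST_PROGRAM.max_ysq == 15


class TestEligibility:
    def test_current_smoker_meeting_pack_years(self):
        p = Person(sex=0, oc_death_age=90,
                   smoking=SmokingHistory(init_age=25, intensity=35.0))
        assert is_eligible(p, 60, parse_label("A55-75-30-15"))

    def test_former_smoker_beyond_ysq_cap(self):
        p = Person(sex=0, oc_death_age=90,
                   smoking=SmokingHistory(init_age=17, quit_age=44,
                                          intensity=30.0))
        # 40.5 pack-years but quit 16 years before assessment
        assert not is_eligible(p, 60, parse_label("A55-75-30-15"))

    def test_never_smoker_never_eligible(self):
        p = Person(sex=0, oc_death_age=90, smoking=SmokingHistory())
        assert not is_eligible(p, 60, parse_label("A45-85-10-25"))

    def test_light_smoker_enters_program_late(self):
        # 20 cpd from age 28: 30 pack-years only at 58
        p = Person(sex=0, oc_death_age=100,
                   smoking=SmokingHistory(init_age=28, intensity=20.0))
        screens = schedule_screens(p, parse_label("A55-75-30-15"))
        assert screens[0] == 58


class TestSchedules:
    @pytest.mark.parametrize("label,expected", [
        ("A55-75-30-15", 21), ("A55-85-30-15", 31), ("B55-85-30-15", 16),
        ("T60-75-40-10", 6),
    ])
    def test_screen_counts_for_always_eligible(self, label, expected):
        p = always_eligible_person()
        assert len(schedule_screens(p, parse_label(label))) == expected

    def test_truncation_at_death(self):
        p = always_eligible_person(oc=70.0)
        screens = schedule_screens(p, parse_label("A55-85-30-15"))
        assert screens == list(range(55, 70))

    def test_start_must_precede_stop(self):
        with pytest.raises(ValueError):
            Program(frequency=1, start_age=80, stop_age=75,
                    min_pack_years=30, max_ysq=15)


@pytest.fixture(scope="module")
def small():
    c = generate_cohort(10_000, 2)
    v = default_variants()[0]
    d = simulate_disease_cohort(c, v, 2)
    return c, d, prepare_overlay(c, d, 2)


class TestOverlay:

    def test_no_screening_reference(self, small):
        c, d, overlay = small
        ref = run_scenario(overlay, None)
        assert ref.screens.sum() == 0
        np.testing.assert_array_equal(ref.lc_death_age, d.lc_death_clinical)

    def test_zero_sensitivity_reduces_to_no_screening(self, small):
        c, d, _ = small
        v0 = dataclasses.replace(default_variants()[0],
                                 sensitivity=CtSensitivity(max_sens=0.0))
        d0 = dataclasses.replace(d, variant=v0)
        overlay = prepare_overlay(c, d0, 2)
        ref = run_scenario(overlay, None)
        arr = run_scenario(overlay, parse_label("A45-85-10-25"))
        assert arr.screens.sum() > 0
        np.testing.assert_array_equal(arr.lc_death_age, ref.lc_death_age)

    def test_annual_versus_biennial(self, small):
        c, d, overlay = small
        annual = run_scenario(overlay, parse_label("A55-85-30-15"))
        biennial = run_scenario(overlay, parse_label("B55-85-30-15"))
        ratio = annual.screens.sum() / biennial.screens.sum()
        assert 1.7 < ratio < 2.2
        oc = c.oc_death_age
        def deaths(a):
            return int(((a.lc_death_age < oc) & (a.lc_death_age < 90)).sum())
        assert deaths(annual) < deaths(biennial)

    def test_most_intensive_program_dominates(self, small):
        """A45-85-10-25 screens a superset of every program's screens and,
        with shared draws, avoids at least as many deaths."""
        c, d, overlay = small
        oc = c.oc_death_age
        top = run_scenario(overlay, parse_label("A45-85-10-25"))
        def deaths(a):
            return int(((a.lc_death_age < oc) & (a.lc_death_age < 90)).sum())
        rng = np.random.default_rng(0)
        programs, _ = program_grid()
        for prog in rng.choice(np.asarray(programs, object), 25, replace=False):
            arr = run_scenario(overlay, prog)
            assert top.screens.sum() >= arr.screens.sum()
            assert deaths(top) <= deaths(arr)
            # detection never later than under the sub-program
            both = np.isfinite(arr.detection_age)
            assert np.all(top.detection_age[both] <= arr.detection_age[both])

    def test_raising_stop_age_never_hurts(self, small):
        c, d, overlay = small
        oc = c.oc_death_age
        def deaths(a):
            return int(((a.lc_death_age < oc) & (a.lc_death_age < 90)).sum())
        for base in ("A55-75-30-15", "B50-75-20-20", "T60-75-40-10"):
            hi = base.replace("-75-", "-85-")
            lo_arr = run_scenario(overlay, parse_label(base))
            hi_arr = run_scenario(overlay, parse_label(hi))
            assert hi_arr.screens.sum() >= lo_arr.screens.sum()
            assert deaths(hi_arr) <= deaths(lo_arr)

    def test_overlay_never_mutates_latent_state(self, small):
        c, d, overlay = small
        oc_before = c.oc_death_age.copy()
        lc_before = d.lc_death_clinical.copy()
        run_scenario(overlay, parse_label("A45-85-10-25"))
        np.testing.assert_array_equal(c.oc_death_age, oc_before)
        np.testing.assert_array_equal(d.lc_death_clinical, lc_before)

    def test_screens_bounded_by_schedule_length(self, small):
        c, d, overlay = small
        arr = run_scenario(overlay, parse_label("B55-85-30-15"))
        assert arr.screens.max() <= 16


class TestOperativeCandidacy:
    def test_filter_validates_curve(self):
        p = always_eligible_person()
        with pytest.raises(ValueError):
            operative_candidacy_filter(p, 70, lambda a: min(a / 50.0, 1.0))
        assert operative_candidacy_filter(p, 70, lambda a: 1.0, u=0.99)
        assert not operative_candidacy_filter(p, 70, lambda a: 0.0, u=0.0)

    def test_candidacy_one_matches_main_analysis(self):
        c = make_cohort(16.0, np.nan, 40.0, 3000)
        v = default_variants()[0]
        d = simulate_disease_cohort(c, v, 3)
        base = run_scenario(prepare_overlay(c, d, 3), parse_label("A55-85-30-15"))
        gated = run_scenario(
            prepare_overlay(c, d, 3, candidacy_curve=lambda a: 1.0),
            parse_label("A55-85-30-15"))
        np.testing.assert_array_equal(base.screens, gated.screens)
        np.testing.assert_array_equal(base.lc_death_age, gated.lc_death_age)

    def test_candidacy_zero_means_no_screens(self):
        c = make_cohort(16.0, np.nan, 40.0, 3000)
        v = default_variants()[0]
        d = simulate_disease_cohort(c, v, 3)
        arr = run_scenario(
            prepare_overlay(c, d, 3, candidacy_curve=lambda a: 0.0),
            parse_label("A45-85-10-25"))
        assert arr.screens.sum() == 0
        assert not np.isfinite(arr.detection_age).any()

    def test_declining_candidacy_reduces_screens_and_benefit(self):
        c = make_cohort(16.0, np.nan, 40.0, 20_000)
        v = default_variants()[0]
        d = simulate_disease_cohort(c, v, 3)
        oc = c.oc_death_age
        def deaths(a):
            return int(((a.lc_death_age < oc) & (a.lc_death_age < 90)).sum())
        curve = lambda a: 1.0 if a <= 75 else max(0.2, 1.0 - 0.1 * (a - 75))
        base = run_scenario(prepare_overlay(c, d, 3), parse_label("A55-85-30-15"))
        gated = run_scenario(prepare_overlay(c, d, 3, candidacy_curve=curve),
                             parse_label("A55-85-30-15"))
        assert gated.screens.sum() < base.screens.sum()
        assert deaths(gated) > deaths(base)     # fewer deaths avoided

    def test_non_monotone_curve_rejected_in_overlay(self):
        c = make_cohort(16.0, np.nan, 40.0, 100)
        v = default_variants()[0]
        d = simulate_disease_cohort(c, v, 3)
        with pytest.raises(ValueError):
            prepare_overlay(c, d, 3,
                            candidacy_curve=lambda a: 0.5 + 0.4 * np.sin(a))


class TestPersonLevelOverlay:
    def test_apply_screening_no_screening_reference(self):
        p = always_eligible_person()
        v = default_variants()[0]
        course = simulate_disease(p, v, rng_or_seed=4)
        rec = apply_screening(p, course, None, v, seed=4)
        assert rec.screen_ages == []
        want = course.lc_death_age_clinical
        assert rec.lc_death_age_screened == want

    def test_apply_screening_counts_follow_schedule(self):
        p = always_eligible_person()
        v = default_variants()[0]
        course = simulate_disease(p, v, rng_or_seed=4)
        rec = apply_screening(p, course, parse_label("A55-75-30-15"), v, seed=4)
        assert len(rec.screen_ages) <= 21
        if rec.detection_age is not None:
            assert rec.detection_age in rec.screen_ages
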