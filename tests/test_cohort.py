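"""Smoking life-course generation, exposure accounting, and mortality."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctscreen import (CohortParams, MortalityTable, Person, SmokingHistory,
                      generate_cohort, pack_years_at, sample_oc_death,
                      years_since_quit_at)
from ctscreen.cohort import (_sample_oc_death_vector, CURRENT, FORMER, NEVER)
from ctscreen.params import MortalityParams


def person(init=None, quit=None, cpd=None, sex=0, oc=85.0):
    return Person(sex=sex, oc_death_age=oc,
                  smoking=SmokingHistory(init_age=init, quit_age=quit,
                                         intensity=cpd))


class TestPackYears:
    @pytest.mark.parametrize("init,quit,cpd,age,expected", [
        (20, 30, 20.0, 30, 10.0),        # 1 pack/day for 10 years
        (20, 30, 20.0, 25, 5.0),
        (None, None, None, 60, 0.0),     # never-smoker
        (17, None, 40.0, 47, 60.0),      # 2 packs/day, 30 years, current
    ])
    def test_scalar_profiles(self, init, quit, cpd, age, expected):
        assert pack_years_at(person(init, quit, cpd), age) == pytest.approx(expected)

    def test_piecewise_intensity(self):
        # 2 packs/day for 15 y then half a pack for 10 y: 30 + 5 = 35
        h = SmokingHistory(init_age=18, quit_age=43,
                           intensity=((18, 40.0), (33, 10.0)))
        assert pack_years_at(h, 43) == pytest.approx(35.0)
        assert pack_years_at(h, 90) == pytest.approx(35.0)

    @given(init=st.floats(12, 30), dur=st.floats(1, 40),
           cpd=st.floats(1, 60), split=st.floats(0.05, 0.95))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_additive_over_interval_splits(self, init, dur, cpd, split):
        """Accrual is invariant to how the smoking interval is split."""
        quit = min(init + dur, 88.0)
        cut = init + split * (quit - init)
        whole = SmokingHistory(init_age=init, quit_age=quit, intensity=cpd)
        parts = SmokingHistory(init_age=init, quit_age=quit,
                               intensity=((init, cpd), (cut, cpd)))
        for age in (init + 0.3 * dur, quit, 89.0):
            age = min(age, 90.0)
            assert pack_years_at(parts, age) == pytest.approx(
                pack_years_at(whole, age), rel=1e-12)

    def test_non_decreasing_in_age(self):
        p = person(17, 50, 30.0)
        py = [pack_years_at(p, a) for a in range(0, 91, 5)]
        assert all(b >= a for a, b in zip(py, py[1:]))


class TestYearsSinceQuit:
    def test_former(self):
        assert years_since_quit_at(person(20, 50, 20.0), 60) == pytest.approx(10)

    def test_current_is_zero(self):
        # convention: a max-YSQ cap never excludes current smokers
        assert years_since_quit_at(person(20, None, 20.0), 60) == 0.0

    def test_never_is_not_applicable(self):
        assert years_since_quit_at(person(), 60) is None


class TestSmokingHistoryInvariants:
    def test_never_smoker_cannot_quit(self):
        with pytest.raises(ValueError):
            SmokingHistory(init_age=None, quit_age=50)

    def test_quit_after_init(self):
        with pytest.raises(ValueError):
            SmokingHistory(init_age=30, quit_age=25, intensity=10.0)

    def test_positive_intensity(self):
        with pytest.raises(ValueError):
            SmokingHistory(init_age=20, intensity=0.0)

    def test_status_sequence(self):
        h = SmokingHistory(init_age=20, quit_age=40, intensity=10.0)
        seq = h.status_sequence()
        assert seq[10] == NEVER and seq[30] == CURRENT and seq[50] == FORMER


class TestGeneration:
    def test_deterministic_for_fixed_seed(self):
        a = generate_cohort(1000, seed=42)
        b = generate_cohort(1000, seed=42)
        for field in ("sex", "init_age", "quit_age", "cpd", "oc_death_age"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_all_statuses_and_sexes_present(self):
        c = generate_cohort(1000, seed=3)
        assert set(np.unique(c.sex)) == {0, 1}
        never = np.isnan(c.init_age)
        former = ~never & ~np.isnan(c.quit_age)
        current = ~never & np.isnan(c.quit_age)
        assert never.any() and former.any() and current.any()

    def test_zero_initiation_gives_all_never_smokers(self):
        p = CohortParams(initiation_prob=tuple(0.0 for _ in range(19)))
        c = generate_cohort(500, seed=1, params=p)
        assert np.isnan(c.init_age).all()
        assert (c.pack_years_matrix(np.arange(45.0, 86.0)) == 0).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_cohort(10, 1, CohortParams(male_fraction=1.5))
        with pytest.raises(ValueError, match="outside"):
            generate_cohort(
                10, 1, CohortParams(initiation_prob=(1.2,) + (0.0,) * 18))

    def test_certain_cessation_stops_all_smoking(self):
        p = CohortParams(cessation_schedule=((0, 0.0), (40, 1.0)))
        c = generate_cohort(2000, seed=5, params=p)
        smoker = ~np.isnan(c.init_age)
        assert np.all(c.quit_age[smoker] == 40.0)
        ysq60 = c.ysq_matrix(np.array([60.0]))[smoker, 0]
        assert np.all(ysq60 == 20.0)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 1)


class TestMortality:
    def test_table_ordering_invariant(self):
        t = MortalityTable.from_params(MortalityParams())
        assert np.all(t.current >= t.never[:, :, None])
        # former between never and current at every interpolation point
        for ysq in (0.0, 5.0, 14.9, 30.0):
            r = t.rate(0, 70, FORMER, quintile=4, ysq=ysq)
            assert t.rate(0, 70, NEVER) <= r <= t.rate(0, 70, CURRENT, 4)

    def test_negative_rate_rejected(self):
        ages = np.arange(0, 5)
        never = np.full((2, 5), -0.1)
        with pytest.raises(ValueError):
            MortalityTable(ages=ages, never=never,
                           current=np.full((2, 5, 5), 0.1))

    def test_zero_hazard_caps_at_terminal_age(self):
        ages = np.arange(0, 111)
        t = MortalityTable(ages=ages, never=np.zeros((2, 111)),
                           current=np.zeros((2, 111, 5)))
        rng = np.random.default_rng(0)
        assert sample_oc_death(person(), t, rng) == t.terminal_age

    def test_constant_hazard_matches_exponential_mean(self):
        lam = 0.2
        ages = np.arange(0, 200)
        t = MortalityTable(ages=ages, never=np.full((2, 200), lam),
                           current=np.full((2, 200, 5), lam))
        rng = np.random.default_rng(1)
        n = 4000
        draws = _sample_oc_death_vector(
            np.zeros(n, np.int8), np.full(n, np.nan), np.full(n, np.nan),
            np.full(n, -1, np.int8), t, rng)
        assert np.mean(draws - 45.0) == pytest.approx(1 / lam, abs=0.35)

    def test_survival_ordering_heavy_current_below_never(self):
        """Other-cause survival: never >= former >= current heavy smokers."""
        t = MortalityTable.from_params(MortalityParams())
        n = 10_000
        strata = {
            "never": (np.nan, np.nan, -1),
            "former": (16.0, 45.0, 4),
            "current": (16.0, np.nan, 4),
        }
        surv = {}
        for name, (init, quit, k) in strata.items():
            rng = np.random.default_rng(7)
            d = _sample_oc_death_vector(
                np.zeros(n, np.int8), np.full(n, init), np.full(n, quit),
                np.full(n, k, np.int8), t, rng)
            surv[name] = d
        grid = np.arange(50, 105, 5)
        for a in grid:
            s_never = (surv["never"] > a).mean()
            s_former = (surv["former"] > a).mean()
            s_current = (surv["current"] > a).mean()
            assert s_never >= s_former - 0.01 >= s_current - 0.02

    def test_person_level_sampler_follows_stratum(self):
        t = MortalityTable.from_params(MortalityParams())
        rng = np.random.default_rng(0)
        d = sample_oc_death(person(16, None, 40.0), t, rng)
        assert 45.0 < d <= t.terminal_age


class TestCohortIO:
    def test_csv_round_trip(self, tmp_path):
        c = generate_cohort(200, 9)
        path = tmp_path / "cohort.csv"
        c.to_csv(path)
        from ctscreen.cohort import Cohort
        back = Cohort.from_csv(path)
        np.testing.assert_array_equal(back.sex, c.sex)
        np.testing.assert_allclose(back.oc_death_age, c.oc_death_age)
        np.testing.assert_allclose(back.init_age, c.init_age)

    def test_person_view(self):
        c = generate_cohort(50, 2)
        i = int(np.flatnonzero(~np.isnan(c.init_age))[0])
        p = c.person(i)
        assert p.rng_stream_id == i
        assert p.smoking.init_age == c.init_age[i]
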