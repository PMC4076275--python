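"""Synthetic smoking life-courses and other-cause mortality for one birth
cohort.

This module generates the shared inputs every model variant consumes:
individual smoking histories (never / current / former, annual time steps,
cigarettes-per-day fixed at initiation) and an other-cause death age drawn
from a smoking-stratified hazard table, for US persons born in 1950 and
followed from age 45 to death or age 90.

Randomness is purpose-keyed: the smoking process and the other-cause death
draw each use an independent stream derived from ``(seed, purpose)``, with
per-person draws indexed by person id. Reusing a cohort across screening
scenarios therefore reuses identical life histories — the common-random-
numbers design that makes "deaths avoided vs no screening" free of
between-arm Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .params import (CohortParams, MortalityParams, ENTRY_AGE, MALE, FEMALE,
                     TRUNCATION_AGE)

NEVER, CURRENT, FORMER = "never", "current", "former"

# purpose ids for the per-purpose RNG streams
_STREAM_SMOKING = 1
_STREAM_OC_DEATH = 2


def _rng(seed: int, purpose: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose, *extra]))


# ---------------------------------------------------------------------------
# Person-level types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmokingHistory:
    """A smoking life-course.

    ``intensity`` is either a single cigarettes/day value (held from
    ``init_age`` to quitting) or a piecewise-constant profile given as
    ``((age, cpd), ...)`` change-points starting at ``init_age``.
    """

    init_age: Optional[float] = None
    quit_age: Optional[float] = None
    intensity: Union[float, tuple, None] = None

    def __post_init__(self):
        if self.init_age is None:
            if self.quit_age is not None or self.intensity is not None:
                raise ValueError("never-smoker must have no quit age/intensity")
        else:
            if self.quit_age is not None and self.quit_age <= self.init_age:
                raise ValueError("former smoker requires init_age < quit_age")
            for _, cpd in self.segments():
                if cpd <= 0:
                    raise ValueError("intensity must be > 0 while smoking")

    def segments(self) -> tuple:
        """((start_age, cpd), ...) pieces of the intensity profile."""
        if self.init_age is None:
            return ()
        if np.isscalar(self.intensity):
            return ((float(self.init_age), float(self.intensity)),)
        segs = tuple((float(a), float(c)) for a, c in self.intensity)
        if not segs or segs[0][0] != self.init_age:
            raise ValueError("intensity profile must start at init_age")
        return segs

    def status_at(self, age: float) -> str:
        if self.init_age is None or age < self.init_age:
            return NEVER
        if self.quit_age is not None and age >= self.quit_age:
            return FORMER
        return CURRENT

    def status_sequence(self, max_age: int = TRUNCATION_AGE) -> list:
        return [self.status_at(a) for a in range(max_age + 1)]


@dataclass(frozen=True)
class Person:
    sex: int                      # MALE or FEMALE
    smoking: SmokingHistory
    oc_death_age: float
    rng_stream_id: int = 0
    birth_year: int = 1950

    def __post_init__(self):
        if self.oc_death_age <= 0:
            raise ValueError("oc_death_age must be positive")


def pack_years_at(person: Union[Person, SmokingHistory], age: float) -> float:
    """Cumulative pack-years smoked by ``age``.

    Additive over age intervals: sum of (cigarettes/day / 20) x years for
    each constant-intensity piece up to min(age, quit_age).
    """
    smoking = person.smoking if isinstance(person, Person) else person
    if not (0.0 <= age <= TRUNCATION_AGE):
        raise ValueError(f"age {age} outside [0, {TRUNCATION_AGE}]")
    segs = smoking.segments()
    if not segs:
        return 0.0
    end = age if smoking.quit_age is None else min(age, smoking.quit_age)
    total = 0.0
    for i, (start, cpd) in enumerate(segs):
        seg_end = segs[i + 1][0] if i + 1 < len(segs) else end
        dur = min(seg_end, end) - start
        if dur > 0:
            total += (cpd / 20.0) * dur
    return total


def years_since_quit_at(person: Union[Person, SmokingHistory],
                        age: float) -> Optional[float]:
    """Years since quitting at ``age``.

    Current smokers report 0 (so a maximum-YSQ eligibility cap never
    excludes them); never-smokers report ``None`` (not applicable).
    """
    smoking = person.smoking if isinstance(person, Person) else person
    if not (0.0 <= age <= TRUNCATION_AGE):
        raise ValueError(f"age {age} outside [0, {TRUNCATION_AGE}]")
    status = smoking.status_at(age)
    if status == NEVER:
        return None
    if status == CURRENT:
        return 0.0
    return age - smoking.quit_age


# ---------------------------------------------------------------------------
# Mortality table
# ---------------------------------------------------------------------------


@dataclass
class MortalityTable:
    """Other-cause hazard by sex x integer age x smoking stratum.

    Strata: never; current smoker by intensity quintile; former smokers are
    interpolated linearly between their quintile's current rate and the
    never rate over ``former_interp_years`` years since quitting.
    """

    ages: np.ndarray              # integer ages, e.g. 0..110
    never: np.ndarray             # (2, A)
    current: np.ndarray           # (2, A, Q)
    former_interp_years: float = 15.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if np.any(self.never < 0) or np.any(self.current < 0):
            raise ValueError("mortality rates must be non-negative")
        if np.any(self.current < self.never[:, :, None] - 1e-15):
            raise ValueError("current-smoker rate must be >= never rate "
                             "at every age within each quintile")

    @property
    def terminal_age(self) -> float:
        return float(self.ages[-1] + 1)

    @classmethod
    def from_params(cls, p: MortalityParams) -> "MortalityTable":
        p.validate()
        ages = np.arange(0, int(p.terminal_age))
        male = p.base_rate_45 * np.exp(p.gompertz_slope * (ages - ENTRY_AGE))
        never = np.stack([male, male * p.female_scale])
        rr = np.asarray(p.current_rr, dtype=float)
        current = never[:, :, None] * rr[None, None, :]
        return cls(ages=ages, never=never, current=current,
                   former_interp_years=p.former_interp_years)

    def rate(self, sex: int, age: float, status: str, quintile: int = 0,
             ysq: float = 0.0) -> float:
        """Hazard for one stratum; former smokers interpolated by YSQ."""
        i = int(np.clip(np.floor(age), self.ages[0], self.ages[-1]))
        if status == NEVER:
            return float(self.never[sex, i])
        cur = float(self.current[sex, i, quintile])
        if status == CURRENT:
            return cur
        w = max(0.0, 1.0 - ysq / self.former_interp_years)
        return float(self.never[sex, i] + w * (cur - self.never[sex, i]))


# ---------------------------------------------------------------------------
# Cohort container (struct of arrays)
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A generated cohort, stored column-wise for vectorized simulation.

    ``init_age``/``quit_age`` are NaN where not applicable (never smokers,
    current smokers). ``intensity_class`` is -1 for never-smokers.
    """

    sex: np.ndarray               # int8, MALE/FEMALE
    init_age: np.ndarray          # float
    quit_age: np.ndarray          # float
    intensity_class: np.ndarray   # int8 index into params.intensity_cpd
    cpd: np.ndarray               # float, 0 for never-smokers
    oc_death_age: np.ndarray      # float
    seed: int
    params: CohortParams

    @property
    def n(self) -> int:
        return self.sex.shape[0]

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n)

    def person(self, i: int) -> Person:
        init = None if np.isnan(self.init_age[i]) else float(self.init_age[i])
        quit = None if np.isnan(self.quit_age[i]) else float(self.quit_age[i])
        smoking = SmokingHistory(
            init_age=init, quit_age=quit,
            intensity=None if init is None else float(self.cpd[i]))
        return Person(sex=int(self.sex[i]), smoking=smoking,
                      oc_death_age=float(self.oc_death_age[i]),
                      rng_stream_id=int(i))

    # vectorized smoking-exposure lookups -----------------------------------

    def pack_years_matrix(self, ages: np.ndarray) -> np.ndarray:
        """(n, len(ages)) cumulative pack-years at each integer age."""
        ages = np.asarray(ages, dtype=float)[None, :]
        init = self.init_age[:, None]
        quit = np.where(np.isnan(self.quit_age), np.inf, self.quit_age)[:, None]
        dur = np.clip(np.minimum(ages, quit) - init, 0.0, None)
        dur = np.where(np.isnan(init), 0.0, dur)
        return (self.cpd[:, None] / 20.0) * dur

    def ysq_matrix(self, ages: np.ndarray) -> np.ndarray:
        """(n, len(ages)) years since quitting; 0 while current, +inf never."""
        ages = np.asarray(ages, dtype=float)[None, :]
        quit = np.where(np.isnan(self.quit_age), np.inf, self.quit_age)[:, None]
        ysq = np.clip(ages - quit, 0.0, None)
        never = np.isnan(self.init_age)[:, None]
        return np.where(never, np.inf, np.where(np.isinf(ysq), 0.0, ysq))

    def never_smoker(self) -> np.ndarray:
        return np.isnan(self.init_age)

    # I/O -------------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "sex": self.sex,
            "init_age": self.init_age, "quit_age": self.quit_age,
            "intensity_class": self.intensity_class, "cpd": self.cpd,
            "oc_death_age": self.oc_death_age,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: Optional[CohortParams] = None,
                 seed: int = -1) -> "Cohort":
        df = pd.read_csv(path)
        return cls(sex=df["sex"].to_numpy(np.int8),
                   init_age=df["init_age"].to_numpy(float),
                   quit_age=df["quit_age"].to_numpy(float),
                   intensity_class=df["intensity_class"].to_numpy(np.int8),
                   cpd=df["cpd"].to_numpy(float),
                   oc_death_age=df["oc_death_age"].to_numpy(float),
                   seed=seed, params=params or CohortParams())


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_cohort(n: int, seed: int,
                    params: Optional[CohortParams] = None) -> Cohort:
    """Generate ``n`` members of the 1950 birth cohort alive at age 45.

    Annual discrete steps: one initiation opportunity per year over the
    initiation ages, one cessation opportunity per year while smoking.
    Other-cause death is sampled from the smoking-stratified hazard table
    conditional on surviving to age 45 (the cohort is defined as the
    population alive at entry).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or CohortParams()
    params.validate()

    rng = _rng(seed, _STREAM_SMOKING)
    sex = (rng.random(n) >= params.male_fraction).astype(np.int8)  # 0=M, 1=F

    # initiation: first age (if any) at which the annual Bernoulli fires
    init_age = np.full(n, np.nan)
    scale = np.where(sex == MALE, 1.0, params.female_initiation_scale)
    for age, p in zip(params.initiation_ages, params.initiation_prob):
        u = rng.random(n)
        start = np.isnan(init_age) & (u < p * scale)
        init_age[start] = age

    # intensity class fixed at initiation
    probs = np.asarray(params.intensity_probs)
    klass = rng.choice(len(probs), size=n, p=probs).astype(np.int8)
    smoker = ~np.isnan(init_age)
    klass[~smoker] = -1
    cpd = np.where(smoker, np.asarray(params.intensity_cpd)[np.clip(klass, 0, None)], 0.0)

    # cessation: one opportunity per year from initiation
    quit_age = np.full(n, np.nan)
    max_age = TRUNCATION_AGE
    for age in range(int(min(params.initiation_ages)), max_age):
        at_risk = smoker & (init_age < age) & np.isnan(quit_age)
        if not at_risk.any():
            continue
        p = params.cessation_prob(np.asarray(float(age)))
        u = rng.random(n)
        quit_age[at_risk & (u < p)] = age

    table = MortalityTable.from_params(params.mortality)
    oc_death_age = _sample_oc_death_vector(
        sex, init_age, quit_age, klass, table,
        _rng(seed, _STREAM_OC_DEATH))

    return Cohort(sex=sex, init_age=init_age, quit_age=quit_age,
                  intensity_class=klass, cpd=cpd, oc_death_age=oc_death_age,
                  seed=seed, params=params)


def _sample_oc_death_vector(sex, init_age, quit_age, klass, table: MortalityTable,
                            rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant-hazard sampling of other-cause death from age 45,
    conditional on being alive at 45, vectorized over persons."""
    n = sex.shape[0]
    e = rng.exponential(size=n)          # target cumulative hazard
    cum = np.zeros(n)
    death = np.full(n, table.terminal_age)
    done = np.zeros(n, dtype=bool)
    quint = np.clip(klass, 0, None)
    quit = np.where(np.isnan(quit_age), np.inf, quit_age)
    smoker = ~np.isnan(init_age)
    for age in range(ENTRY_AGE, int(table.terminal_age)):
        never_r = table.never[sex, age]
        cur_r = table.current[sex, age, quint]
        ysq = np.clip(age + 0.5 - quit, 0.0, None)
        w = np.clip(1.0 - ysq / table.former_interp_years, 0.0, 1.0)
        former = smoker & (quit <= age + 0.5)
        h = np.where(smoker & ~former, cur_r,
                     np.where(former, never_r + w * (cur_r - never_r), never_r))
        crossing = ~done & (cum + h >= e)
        frac = np.where(h > 0, (e - cum) / np.where(h > 0, h, 1.0), 1.0)
        death[crossing] = age + np.clip(frac[crossing], 0.0, 1.0)
        done |= crossing
        cum += h
        if done.all():
            break
    return death


def sample_oc_death(person: Person, table: MortalityTable,
                    rng: np.random.Generator) -> float:
    """Draw one other-cause death age for ``person`` from ``table``.

    Follows the person's evolving stratum (current until quit, then former
    interpolated by years since quitting). Deaths are capped at the table's
    terminal age when the cumulative hazard is never exceeded.
    """
    table.validate()
    s = person.smoking
    sex = np.array([person.sex], dtype=np.int8)
    init = np.array([np.nan if s.init_age is None else s.init_age])
    quit = np.array([np.nan if s.quit_age is None else s.quit_age])
    # map the person's cpd onto the nearest default quintile for table lookup
    if s.init_age is None:
        k = np.array([-1], dtype=np.int8)
    else:
        cpds = np.asarray(CohortParams().intensity_cpd)
        mean_cpd = np.mean([c for _, c in s.segments()])
        k = np.array([int(np.argmin(np.abs(cpds - mean_cpd)))], dtype=np.int8)
    return float(_sample_oc_death_vector(sex, init, quit, k, table, rng)[0])
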