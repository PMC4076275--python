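"""Screening programs, eligibility, and the scenario overlay.

The evaluated design space crosses screening frequency (annual, biennial,
triennial), start age (45/50/55/60), stop age (75/80/85), minimum pack-years
(10/20/30/40) and maximum years since quitting (10/15/20/25) — 576 programs
— plus two reference scenarios: no screening, and an approximation of the
National Lung Screening Trial (three annual screens at ages 62-64 for
smokers with >= 30 pack-years and <= 15 years since quitting).

Eligibility is assessed annually at each candidate screen age: a person must
meet *both* the pack-year minimum and (former smokers only) the
years-since-quit maximum, so light smokers may enter a program late and
former smokers may age out before the stop age. Adherence is perfect.

Each scenario is a deterministic overlay on the latent disease course
simulated once per (cohort, variant): screens never alter the underlying
trajectory, and all scenarios share the same per-person-per-age detection
draws (common random numbers), so scenario differences reflect only the
program design.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .cohort import Cohort, Person, pack_years_at, years_since_quit_at
from .natural_history import DiseaseArrays, DiseaseCourse
from .params import (EARLY, MODE_SCREEN, SCREEN_AGE_MAX, SCREEN_AGE_MIN,
                     TRUNCATION_AGE, ModelVariant)

_STREAM_SCREEN = 4
_STREAM_FOLLOWUP = 5
_STREAM_CANDIDACY = 6

FREQUENCIES = {"A": 1, "B": 2, "T": 3}
_FREQ_CODE = {1: "A", 2: "B", 3: "T"}

START_AGES = (45, 50, 55, 60)
STOP_AGES = (75, 80, 85)
MIN_PACK_YEARS = (10, 20, 30, 40)
MAX_YSQ = (10, 15, 20, 25)

NO_SCREENING = "none"
NLST_LABEL = "NLST"


def _rng(seed: int, purpose: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose, *extra]))


@dataclass(frozen=True)
class Program:
    """One screening program, labelled ``{A|B|T}start-stop-minPY-maxYSQ``."""

    frequency: int                # years between screens: 1, 2 or 3
    start_age: int
    stop_age: int
    min_pack_years: float
    max_ysq: float
    label: str = field(default="")

    def __post_init__(self):
        if self.frequency not in (1, 2, 3):
            raise ValueError("frequency must be 1, 2 or 3 years")
        if self.start_age >= self.stop_age:
            raise ValueError("start_age must be < stop_age")
        if not self.label:
            object.__setattr__(self, "label", format_label(self))

    def candidate_ages(self) -> np.ndarray:
        """Scheduled screen ages: start, start+f, ..., <= stop."""
        return np.arange(self.start_age, self.stop_age + 1, self.frequency)


def format_label(p: Program) -> str:
    return (f"{_FREQ_CODE[p.frequency]}{p.start_age}-{p.stop_age}-"
            f"{p.min_pack_years:g}-{p.max_ysq:g}")


def parse_label(label: str) -> Program:
    """Parse a canonical shorthand like ``"B55-85-20-15"``."""
    m = re.fullmatch(r"([ABT])(\d+)-(\d+)-(\d+(?:\.\d+)?)-(\d+(?:\.\d+)?)",
                     label.strip())
    if not m:
        raise ValueError(f"not a valid program label: {label!r}")
    return Program(frequency=FREQUENCIES[m.group(1)],
                   start_age=int(m.group(2)), stop_age=int(m.group(3)),
                   min_pack_years=float(m.group(4)),
                   max_ysq=float(m.group(5)))


NLST_PROGRAM = Program(frequency=1, start_age=62, stop_age=64,
                       min_pack_years=30, max_ysq=15, label=NLST_LABEL)


def program_grid() -> tuple[list[Program], list[str]]:
    """The 576 programs plus the two reference scenarios.

    Returns ``(programs, reference_labels)`` where the references are the
    no-screening scenario and the NLST approximation.
    """
    programs = [
        Program(frequency=f, start_age=a0, stop_age=a1,
                min_pack_years=py, max_ysq=ysq)
        for f, a0, a1, py, ysq in itertools.product(
            (1, 2, 3), START_AGES, STOP_AGES, MIN_PACK_YEARS, MAX_YSQ)
    ]
    return programs, [NO_SCREENING, NLST_LABEL]


def is_eligible(person: Person, age: float, program: Program) -> bool:
    """Annual eligibility assessment at ``age``.

    True iff accumulated pack-years meet the program minimum AND the person
    is a current smoker or a former smoker within the years-since-quit cap.
    Never-smokers are never eligible.
    """
    if not (program.start_age <= age <= program.stop_age):
        raise ValueError("eligibility is assessed inside [start_age, stop_age]")
    ysq = years_since_quit_at(person, age)
    if ysq is None:        # never-smoker
        return False
    return (pack_years_at(person, age) >= program.min_pack_years
            and ysq <= program.max_ysq)


def schedule_screens(person: Person, program: Program,
                     undiagnosed_until: float = np.inf) -> list[int]:
    """Ages at which ``person`` is actually screened under perfect adherence:
    scheduled, alive, undiagnosed and eligible at each candidate age."""
    out = []
    for age in program.candidate_ages():
        if age >= min(person.oc_death_age, undiagnosed_until, TRUNCATION_AGE):
            continue
        if is_eligible(person, age, program):
            out.append(int(age))
    return out


def operative_candidacy_filter(person: Person, age: float,
                               candidacy_curve: Callable[[float], float],
                               u: float = 0.0) -> bool:
    """Persistent operative-candidacy gate (a comorbidity overlay).

    ``candidacy_curve`` maps age to the probability of still being an
    operative candidate and must be non-increasing; ``u`` is the person's
    persistent uniform draw, so once lost candidacy never returns.
    """
    ages = np.arange(0.0, TRUNCATION_AGE + 1.0)
    c = np.asarray([candidacy_curve(a) for a in ages], dtype=float)
    if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
        raise ValueError("candidacy probabilities must lie in [0, 1]")
    if np.any(np.diff(c) > 1e-12):
        raise ValueError("candidacy curve must be non-increasing in age")
    return u < candidacy_curve(age)


# ---------------------------------------------------------------------------
# Vectorized overlay
# ---------------------------------------------------------------------------

SCREEN_AGES = np.arange(SCREEN_AGE_MIN, SCREEN_AGE_MAX + 1)   # 45..85


@dataclass
class Overlay:
    """Precomputed, scenario-independent state for one (cohort, variant).

    Holds the latent course plus everything the per-scenario pass needs:
    pack-year / years-since-quit lookups at integer screen ages, tumor
    diameter and stage at those ages, the shared detection and follow-up
    draws, and the clinical (no-screening) death ages.
    """

    cohort: Cohort
    disease: DiseaseArrays
    pack_years: np.ndarray        # (n, A) at SCREEN_AGES
    ysq: np.ndarray               # (n, A); inf for never-smokers
    diameter: np.ndarray          # (n, A) mm, 0 when no tumor >= 1 mm
    stage_at: np.ndarray          # (n, A) int8 EARLY/LATE
    would_detect: np.ndarray      # (n, A) bool: sensitivity draw succeeds
    fp_followups: np.ndarray      # (n, A) int16 follow-up exams if FP workup
    tp_followups: np.ndarray      # (n,) int16 follow-up exams on detection
    death_clinical: np.ndarray    # (n,) min(oc, clinical lc death)
    candidacy_ok: np.ndarray      # (n, A) bool operative-candidacy gate
    seed: int

    @property
    def n(self) -> int:
        return self.cohort.n


def prepare_overlay(cohort: Cohort, disease: DiseaseArrays, seed: int,
                    candidacy_curve: Optional[Callable[[float], float]] = None,
                    ) -> Overlay:
    variant = disease.variant
    n = cohort.n
    ages = SCREEN_AGES.astype(float)

    pack_years = cohort.pack_years_matrix(ages)
    ysq = cohort.ysq_matrix(ages)

    rel = ages[None, :] - disease.t1mm[:, None]
    diameter = np.where(rel >= 0, np.exp(disease.growth_rate[:, None]
                                         * np.maximum(rel, 0.0)), 0.0)
    stage_at = (diameter >= disease.stage_threshold[:, None]).astype(np.int8)

    rng = _rng(seed, _STREAM_SCREEN, variant.stream_id)
    u_detect = rng.random((n, ages.size))
    sens = variant.sensitivity.prob(diameter)
    would_detect = u_detect < sens

    rng_fu = _rng(seed, _STREAM_FOLLOWUP, variant.stream_id)
    fp_flag = rng_fu.random((n, ages.size)) < variant.followup.fp_prob
    fp_counts = 1 + rng_fu.poisson(variant.followup.fp_extra_mean,
                                   size=(n, ages.size))
    fp_followups = np.where(fp_flag, fp_counts, 0).astype(np.int16)
    tp_followups = (variant.followup.tp_base
                    + rng_fu.poisson(variant.followup.tp_extra_mean, size=n)
                    ).astype(np.int16)

    death_clinical = np.minimum(cohort.oc_death_age,
                                disease.lc_death_clinical)

    if candidacy_curve is None:
        candidacy_ok = np.ones((n, ages.size), dtype=bool)
    else:
        curve = np.asarray([candidacy_curve(a) for a in ages], dtype=float)
        if np.any(np.diff(curve) > 1e-12):
            raise ValueError("candidacy curve must be non-increasing in age")
        u = _rng(seed, _STREAM_CANDIDACY).random(n)
        candidacy_ok = u[:, None] < curve[None, :]

    return Overlay(cohort=cohort, disease=disease, pack_years=pack_years,
                   ysq=ysq, diameter=diameter, stage_at=stage_at,
                   would_detect=would_detect, fp_followups=fp_followups,
                   tp_followups=tp_followups, death_clinical=death_clinical,
                   candidacy_ok=candidacy_ok, seed=seed)


@dataclass
class ScenarioArrays:
    """Per-person outcome of one scenario (all lengths n)."""

    label: str
    screens: np.ndarray           # int16 counted CT screens
    followups: np.ndarray         # int16 follow-up exams (not screens)
    detection_age: np.ndarray     # float, inf if never screen-detected
    detected_stage: np.ndarray    # int8, -1 if not detected
    lc_death_age: np.ndarray      # float, inf if no lung-cancer death
    death_age: np.ndarray         # min(oc death, lc death)


def run_scenario(overlay: Overlay, program: Optional[Program]) -> ScenarioArrays:
    """Overlay one program (or the no-screening reference for ``None``)."""
    n = overlay.n
    oc = overlay.cohort.oc_death_age
    d = overlay.disease
    variant = d.variant

    if program is None:
        lc = d.lc_death_clinical
        return ScenarioArrays(
            label=NO_SCREENING,
            screens=np.zeros(n, np.int16), followups=np.zeros(n, np.int16),
            detection_age=np.full(n, np.inf),
            detected_stage=np.full(n, -1, np.int8),
            lc_death_age=lc, death_age=np.minimum(oc, lc))

    screens = np.zeros(n, np.int16)
    followups = np.zeros(n, np.int16)
    detection_age = np.full(n, np.inf)
    detected_stage = np.full(n, -1, np.int8)
    undetected = np.ones(n, dtype=bool)

    clin_dx = d.clinical_dx_age
    for age in program.candidate_ages():
        ai = int(age - SCREEN_AGE_MIN)
        eligible = ((overlay.pack_years[:, ai] >= program.min_pack_years)
                    & (overlay.ysq[:, ai] <= program.max_ysq)
                    & overlay.candidacy_ok[:, ai])
        active = (undetected & eligible
                  & (age < overlay.death_clinical) & (age < clin_dx))
        screens[active] += 1
        hit = active & overlay.would_detect[:, ai]
        detection_age[hit] = age
        detected_stage[hit] = overlay.stage_at[hit, ai]
        undetected &= ~hit
        miss = active & ~hit
        followups[miss] += overlay.fp_followups[miss, ai]

    detected = ~undetected
    followups[detected] += overlay.tp_followups[detected]

    cure_frac = variant.survival.cure_fraction(
        np.where(detected, detected_stage, EARLY), MODE_SCREEN,
        np.where(detected, detection_age, 0.0))
    cured_screen = detected & (d.u_cure < cure_frac)
    lc_death = np.where(cured_screen, np.inf, d.lc_death_clinical)

    return ScenarioArrays(label=program.label, screens=screens,
                          followups=followups, detection_age=detection_age,
                          detected_stage=detected_stage,
                          lc_death_age=lc_death,
                          death_age=np.minimum(oc, lc_death))


@dataclass
class ScreeningRecord:
    """Per-person screening record (single-person view of a scenario)."""

    screen_ages: list
    detection_age: Optional[float]
    detected_stage: Optional[int]
    followup_exam_count: int
    lc_death_age_screened: Optional[float]


def apply_screening(person: Person, course: DiseaseCourse, program,
                    variant: ModelVariant, seed: int = 0) -> ScreeningRecord:
    """Overlay one program on one person's latent course.

    ``program=None`` is the no-screening reference: no screens, outcomes
    identical to the clinical course. The latent course is never modified.
    """
    from .params import CohortParams
    s = person.smoking
    cohort = Cohort(
        sex=np.array([person.sex], np.int8),
        init_age=np.array([np.nan if s.init_age is None else s.init_age]),
        quit_age=np.array([np.nan if s.quit_age is None else s.quit_age]),
        intensity_class=np.array([-1 if s.init_age is None else 0], np.int8),
        cpd=np.array([0.0 if s.init_age is None
                      else np.mean([c for _, c in s.segments()])]),
        oc_death_age=np.array([person.oc_death_age]),
        seed=seed, params=CohortParams())
    disease = _course_to_arrays(course, variant)
    overlay = prepare_overlay(cohort, disease, seed)
    arr = run_scenario(overlay, program)
    det = float(arr.detection_age[0])
    # the detecting screen itself occurs while still undiagnosed
    undiagnosed_until = min(
        det + 0.5 if np.isfinite(det) else np.inf,
        np.inf if course.clinical_dx_age is None else course.clinical_dx_age)
    screen_ages = (schedule_screens(person, program,
                                    undiagnosed_until=undiagnosed_until)
                   if program is not None else [])
    det = arr.detection_age[0]
    lc = arr.lc_death_age[0]
    return ScreeningRecord(
        screen_ages=screen_ages,
        detection_age=None if np.isinf(det) else float(det),
        detected_stage=None if arr.detected_stage[0] < 0 else int(arr.detected_stage[0]),
        followup_exam_count=int(arr.followups[0]),
        lc_death_age_screened=None if np.isinf(lc) else float(lc))


def _course_to_arrays(course: DiseaseCourse, variant: ModelVariant) -> DiseaseArrays:
    none = course.onset_age is None
    inf = np.array([np.inf])
    lc = course.lc_death_age_clinical
    return DiseaseArrays(
        onset_age=inf.copy() if none else np.array([course.onset_age]),
        histology=np.array([0 if course.histology is None else course.histology],
                           np.int8),
        growth_rate=np.array([course.growth_rate or 1.0]),
        t1mm=inf.copy() if course.t1mm is None else np.array([course.t1mm]),
        clinical_dx_age=(inf.copy() if course.clinical_dx_age is None
                         else np.array([course.clinical_dx_age])),
        dx_diameter=np.array([0.0]),
        stage_threshold=np.array([course.stage_threshold or np.inf]),
        stage_clinical=np.array([course.stage_at_clinical_dx or 0], np.int8),
        u_cure=np.array([1.0 if course.u_cure is None else course.u_cure]),
        cured_clinical=np.array([course.clinical_dx_age is not None and lc is None]),
        lc_death_clinical=inf.copy() if lc is None else np.array([lc]),
        variant=variant)
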