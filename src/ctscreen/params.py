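"""Parameter containers, shipped defaults, and config-file I/O.

All tunable quantities of the simulation live here: the smoking life-course
generator, the smoking-stratified other-cause mortality table, the two-stage
clonal expansion (TSCE) carcinogenesis parameters, tumor growth / detection /
staging, the screening-effectiveness (cure or stage-shift) survival model,
and the five shipped model variants that stand in for an ensemble of
independently built natural-history models.

Defaults were fixed once by the calibration script (``scripts/calibrate.py``)
so that the no-screening scenario yields roughly 3,700 lifetime lung-cancer
deaths per 100,000 cohort members alive at age 45, with smoking prevalence
and pack-year accumulation plausible for the US cohort born in 1950.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import yaml

# Follow-up window of the simulated life course. Persons are followed from
# age 45 (cohort entry) to death or age 90; screening may occur at integer
# ages 45..85 (the widest program grid).
ENTRY_AGE = 45
TRUNCATION_AGE = 90
SCREEN_AGE_MIN = 45
SCREEN_AGE_MAX = 85

MALE, FEMALE = 0, 1
EARLY, LATE = 0, 1
NSCLC, SCLC = 0, 1
MODE_CLINICAL, MODE_SCREEN = "clinical", "screen"


# ---------------------------------------------------------------------------
# Smoking life-course generator
# ---------------------------------------------------------------------------

# Annual probability of starting to smoke at ages 12..30 (males; females are
# scaled down). The hump shape peaks in the late teens, which is what the
# initiation curves estimated for mid-century US birth cohorts look like.
INITIATION_AGES = np.arange(12, 31)
_DEFAULT_INITIATION = (
    0.020, 0.030, 0.050, 0.080, 0.110, 0.130, 0.120, 0.095, 0.075,
    0.055, 0.040, 0.028, 0.018, 0.012, 0.009, 0.006, 0.005, 0.004, 0.003,
)

# Annual probability of quitting, by attained-age band [lower bound, prob].
_DEFAULT_CESSATION = ((0, 0.010), (30, 0.020), (40, 0.030), (50, 0.045),
                      (60, 0.060), (70, 0.080))


@dataclass
class MortalityParams:
    """Other-cause (non-lung-cancer) mortality, stratified by smoking.

    The never-smoker hazard is Gompertz in age; current smokers carry a
    relative risk by cigarettes-per-day quintile; former smokers are linearly
    interpolated from their quintile's current rate back to the never rate
    over ``former_interp_years`` years since quitting.
    """

    base_rate_45: float = 2.0e-3      # never-smoker hazard at age 45 (male), /yr
    gompertz_slope: float = 0.088     # log-hazard slope per year of age
    female_scale: float = 0.65        # female/male never-smoker hazard ratio
    current_rr: tuple = (1.4, 1.6, 1.9, 2.2, 2.6)   # by intensity quintile
    former_interp_years: float = 15.0
    terminal_age: float = 110.0       # hazard table ends here; deaths capped

    def validate(self) -> None:
        if self.base_rate_45 < 0 or self.female_scale < 0:
            raise ValueError("mortality rates must be non-negative")
        if any(r < 1.0 for r in self.current_rr):
            raise ValueError("current-smoker relative risks must be >= 1")
        if self.former_interp_years <= 0:
            raise ValueError("former_interp_years must be positive")


@dataclass
class CohortParams:
    """Parameters of the synthetic smoking-history generator.

    Discrete annual time steps: one initiation opportunity per year over
    ``initiation_ages``, one cessation opportunity per year while smoking,
    cigarettes/day drawn once at initiation from a five-class (quintile
    style) distribution and held fixed.
    """

    male_fraction: float = 0.5
    initiation_ages: tuple = tuple(int(a) for a in INITIATION_AGES)
    initiation_prob: tuple = _DEFAULT_INITIATION
    female_initiation_scale: float = 0.75
    cessation_schedule: tuple = _DEFAULT_CESSATION  # (age lower bound, annual prob)
    intensity_cpd: tuple = (5.0, 10.0, 20.0, 30.0, 40.0)
    intensity_probs: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    mortality: MortalityParams = field(default_factory=MortalityParams)

    def validate(self) -> None:
        probs = list(self.initiation_prob) + [p for _, p in self.cessation_schedule]
        probs += list(self.intensity_probs) + [self.male_fraction,
                                               self.female_initiation_scale]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"probability parameter {p!r} outside [0, 1]")
        if len(self.initiation_prob) != len(self.initiation_ages):
            raise ValueError("initiation_prob must match initiation_ages")
        if len(self.intensity_cpd) != len(self.intensity_probs):
            raise ValueError("intensity class values/probs length mismatch")
        if abs(sum(self.intensity_probs) - 1.0) > 1e-9:
            raise ValueError("intensity_probs must sum to 1")
        if any(c <= 0 for c in self.intensity_cpd):
            raise ValueError("cigarettes/day must be positive while smoking")
        self.mortality.validate()

    def cessation_prob(self, age: np.ndarray) -> np.ndarray:
        """Annual quit probability at (integer) age, from the step schedule."""
        age = np.asarray(age, dtype=float)
        out = np.zeros_like(age)
        for lo, p in self.cessation_schedule:
            out = np.where(age >= lo, p, out)
        return out


# ---------------------------------------------------------------------------
# Natural history: TSCE dose response, tumor growth, detection, staging
# ---------------------------------------------------------------------------


@dataclass
class TsceParams:
    """Two-stage clonal expansion parameters with linear dose response.

    ``nu`` aggregates the normal-cell pool times the per-cell initiation
    rate (initiated clones per year); ``alpha``/``beta`` are the division and
    death/differentiation rates of initiated cells; ``mu`` is the malignant
    transformation rate per initiated cell-year. While a person smokes
    ``d`` cigarettes/day, nu and mu are multiplied by ``1 + coef * d/20`` and
    the net clonal growth ``alpha - beta`` by ``1 + coef_growth * d/20``
    (holding alpha fixed). ``lag`` is the fixed delay from the first
    surviving malignant cell to a 1 mm tumor.
    """

    nu: float = 1.75             # initiated clones / year, never-smoker
    alpha: float = 3.0           # divisions / year
    beta: float = 2.95           # deaths / year (never-smoker)
    mu: float = 1.0e-7           # transformations / clone-year (scale only)
    coef_nu: float = 1.0
    coef_growth: float = 1.3
    coef_mu: float = 1.0
    lag: float = 2.0             # years, malignant cell -> 1 mm tumor

    def validate(self) -> None:
        if min(self.nu, self.alpha, self.beta, self.mu) < 0:
            raise ValueError("TSCE rates must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if min(self.coef_nu, self.coef_growth, self.coef_mu) < 0:
            raise ValueError("dose coefficients must be non-negative "
                             "(multipliers >= 1 at positive dose)")

    def at_dose(self, cpd):
        """(nu, alpha, beta, mu) while smoking ``cpd`` cigarettes per day."""
        d = np.asarray(cpd, dtype=float) / 20.0
        nu = self.nu * (1.0 + self.coef_nu * d)
        mu = self.mu * (1.0 + self.coef_mu * d)
        g = (self.alpha - self.beta) * (1.0 + self.coef_growth * d)
        beta = self.alpha - g
        alpha = np.full_like(nu, self.alpha)
        return nu, alpha, beta, mu


@dataclass
class GrowthParams:
    """Exponential tumor growth in diameter from 1 mm at onset + lag."""

    rate_nsclc: float = 1.05     # diameter e-folding rate, /yr
    rate_sclc: float = 2.00      # /yr (small-cell grows much faster)
    sigma: float = 0.30          # lognormal person-level spread of the rate

    def validate(self) -> None:
        if min(self.rate_nsclc, self.rate_sclc) <= 0 or self.sigma < 0:
            raise ValueError("growth rates must be positive")


@dataclass
class DetectionParams:
    """Size-dependent hazard of symptomatic (clinical) diagnosis."""

    rate_at_10mm: float = 0.10   # /yr when the tumor is 10 mm
    size_power: float = 2.0      # hazard ~ (d / 10mm) ** size_power


@dataclass
class StageParams:
    """Early/late stage assignment: late once diameter crosses a per-person
    lognormal threshold (median ``threshold_median_mm``)."""

    threshold_median_mm: float = 22.0
    threshold_sigma: float = 0.6


@dataclass
class CtSensitivity:
    """CT screen sensitivity: logistic in diameter above a hard floor."""

    floor_mm: float = 2.0
    midpoint_mm: float = 7.5
    width_mm: float = 2.0
    max_sens: float = 0.91

    def prob(self, diameter_mm: np.ndarray) -> np.ndarray:
        d = np.asarray(diameter_mm, dtype=float)
        p = self.max_sens / (1.0 + np.exp(-(d - self.midpoint_mm) / self.width_mm))
        return np.where(d >= self.floor_mm, p, 0.0)


@dataclass
class SurvivalModel:
    """Post-diagnosis survival: stage/mode-specific cure fractions, with the
    non-cured dying on the clinical-diagnosis clock (lead-time corrected).

    Two effectiveness mechanisms are supported:

    * ``"cure"`` — cure fraction depends on stage *and* detection mode; the
      screen-detected fractions must dominate the clinical ones.
    * ``"stage-shift"`` — cure fraction depends on stage only (same for both
      modes) times a non-increasing age-at-diagnosis factor, so any benefit
      of screening comes from catching tumors at an earlier stage/age.
    """

    mechanism: str = "cure"
    cure_clinical: tuple = (0.35, 0.03)       # (early, late)
    cure_screen: tuple = (0.41, 0.035)        # (early, late)
    stage_cure: tuple = (0.40, 0.035)         # stage-shift mechanism
    age_ref: float = 60.0
    age_slope: float = 0.0                    # per year past age_ref
    age_floor: float = 0.5
    mean_survival: tuple = (3.5, 1.3)         # years if not cured, (early, late)

    def validate(self) -> None:
        for c in (*self.cure_clinical, *self.cure_screen, *self.stage_cure):
            if not (0.0 <= c <= 1.0):
                raise ValueError("cure fractions must lie in [0, 1]")
        if self.mechanism not in ("cure", "stage-shift"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "cure":
            if (self.cure_screen[EARLY] < self.cure_clinical[EARLY]
                    or self.cure_screen[LATE] < self.cure_clinical[LATE]):
                raise ValueError("screen-detected cure fraction must be >= "
                                 "clinically detected, per stage")
        if self.age_slope < 0 or not (0.0 <= self.age_floor <= 1.0):
            raise ValueError("age adjustment must be non-increasing in age")

    def age_factor(self, dx_age):
        f = 1.0 - self.age_slope * np.maximum(
            np.asarray(dx_age, float) - self.age_ref, 0.0)
        return np.clip(f, self.age_floor, 1.0)

    def cure_fraction(self, stage, mode: str, dx_age):
        """Cure probability for a case of ``stage`` detected via ``mode``."""
        stage = np.asarray(stage)
        if np.any((stage != EARLY) & (stage != LATE)):
            raise ValueError("unknown stage class (use EARLY=0 or LATE=1)")
        if mode not in (MODE_CLINICAL, MODE_SCREEN):
            raise ValueError(f"unknown detection mode {mode!r}")
        if self.mechanism == "stage-shift":
            base = np.where(stage == EARLY, self.stage_cure[EARLY],
                            self.stage_cure[LATE])
            return base * self.age_factor(dx_age)
        table = self.cure_screen if mode == MODE_SCREEN else self.cure_clinical
        return np.where(stage == EARLY, table[EARLY], table[LATE])


@dataclass
class FollowupParams:
    """Follow-up CT exams triggered by positive screens (not counted as
    screens). False-positive opportunity tuned to an NLST-like ~24% of
    screening rounds requiring some follow-up."""

    fp_prob: float = 0.23        # per negative screen
    fp_extra_mean: float = 0.8   # extra exams beyond the first, Poisson mean
    tp_base: int = 2             # exams per true-positive pathway
    tp_extra_mean: float = 1.0


@dataclass
class HistologyParams:
    sclc_prob_male: float = 0.18
    sclc_prob_female: float = 0.14


@dataclass
class ModelVariant:
    """One complete natural-history + effectiveness parameterization.

    The shipped five variants emulate an ensemble of independently developed
    models so that the cross-model consensus machinery can be exercised; they
    are this package's own constructs, not reproductions of any external
    model's parameter set.
    """

    name: str
    stream_id: int = 0
    tsce: TsceParams = field(default_factory=TsceParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    stage: StageParams = field(default_factory=StageParams)
    sensitivity: CtSensitivity = field(default_factory=CtSensitivity)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    followup: FollowupParams = field(default_factory=FollowupParams)
    histology: HistologyParams = field(default_factory=HistologyParams)

    def validate(self) -> None:
        self.tsce.validate()
        self.growth.validate()
        self.survival.validate()


def default_variants() -> list[ModelVariant]:
    """The five shipped model variants.

    They differ in dose response, tumor growth, cure fractions and — for the
    last one — the effectiveness mechanism (stage shift with an age
    adjustment), spanning a plausible range of no-screening mortality.
    """
    base = TsceParams()
    variants = [
        ModelVariant(name="V1-cure-central", stream_id=0),
        ModelVariant(
            name="V2-cure-aggressive", stream_id=1,
            tsce=dataclasses.replace(base, nu=base.nu * 1.10, coef_mu=1.2),
            growth=GrowthParams(rate_nsclc=1.30, rate_sclc=2.3),
            survival=SurvivalModel(cure_clinical=(0.30, 0.02),
                                   cure_screen=(0.37, 0.03),
                                   mean_survival=(3.0, 1.0)),
        ),
        ModelVariant(
            name="V3-cure-indolent", stream_id=2,
            tsce=dataclasses.replace(base, nu=base.nu * 0.90, coef_growth=1.15),
            growth=GrowthParams(rate_nsclc=0.80, rate_sclc=1.6),
            survival=SurvivalModel(cure_clinical=(0.40, 0.04),
                                   cure_screen=(0.50, 0.06),
                                   mean_survival=(4.0, 1.5)),
            stage=StageParams(threshold_median_mm=25.0),
        ),
        ModelVariant(
            name="V4-cure-dose-heavy", stream_id=3,
            tsce=dataclasses.replace(base, nu=base.nu * 0.82, coef_nu=1.5,
                                     coef_growth=1.45, coef_mu=0.8),
            survival=SurvivalModel(cure_clinical=(0.33, 0.03),
                                   cure_screen=(0.40, 0.04)),
            sensitivity=CtSensitivity(midpoint_mm=9.0),
        ),
        ModelVariant(
            name="V5-stage-shift-age", stream_id=4,
            tsce=dataclasses.replace(base, nu=base.nu * 1.08),
            survival=SurvivalModel(mechanism="stage-shift",
                                   stage_cure=(0.42, 0.035),
                                   age_slope=0.008, age_floor=0.6),
        ),
    ]
    for v in variants:
        v.validate()
    return variants


# ---------------------------------------------------------------------------
# Config-file I/O (plain YAML of nested dataclasses)
# ---------------------------------------------------------------------------

_NESTED = {
    "mortality": MortalityParams,
    "tsce": TsceParams,
    "growth": GrowthParams,
    "detection": DetectionParams,
    "stage": StageParams,
    "sensitivity": CtSensitivity,
    "survival": SurvivalModel,
    "followup": FollowupParams,
    "histology": HistologyParams,
}


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = _from_dict(_NESTED[f.name], v)
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def to_dict(params) -> dict:
    return dataclasses.asdict(params)


def save_params(params, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


def load_cohort_params(path) -> CohortParams:
    with open(path) as fh:
        p = _from_dict(CohortParams, yaml.safe_load(fh))
    p.validate()
    return p


def load_variant(path) -> ModelVariant:
    with open(path) as fh:
        v = _from_dict(ModelVariant, yaml.safe_load(fh))
    v.validate()
    return v
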