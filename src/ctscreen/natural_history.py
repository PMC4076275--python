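"""Latent lung-cancer natural history.

Malignant onset follows a two-stage clonal expansion (TSCE) model driven by
the person's smoking history: normal cells seed initiated clones at rate
``nu``, initiated cells divide/die at ``alpha``/``beta`` and transform at
``mu``, with smoking multiplying ``nu``, ``mu`` and the net clonal growth
``alpha - beta``. Parameters are piecewise constant on the person's smoking
segments, so the exact survival and hazard of first malignant transformation
have closed forms, derived from the Riccati equation satisfied by the
probability that a single initiated clone never produces a malignant cell.

After onset (plus a fixed lag to reach 1 mm) tumors grow exponentially in
diameter; symptomatic (clinical) diagnosis occurs via a size-dependent
hazard; stage (early/late) is assigned by comparing the diameter at
diagnosis to a per-person lognormal threshold; and lung-cancer death for
non-cured cases occurs a random time after clinical diagnosis. Screening
(overlaid elsewhere) can only change outcomes through the cure mechanism:
non-cured screen-detected cases die exactly when they would have died under
clinical diagnosis, so lead time by itself confers no benefit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .cohort import Cohort, Person, SmokingHistory
from .params import (EARLY, LATE, MALE, MODE_CLINICAL, ENTRY_AGE, SCLC,
                     TRUNCATION_AGE, ModelVariant, SurvivalModel, TsceParams)

_STREAM_DISEASE = 3

def _rng(seed: int, purpose: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), purpose, *extra]))


# ---------------------------------------------------------------------------
# TSCE hazard / cumulative hazard, exact piecewise-constant solution
# ---------------------------------------------------------------------------
#
# Let Phi(s, t) be the probability that a clone initiated at time s produces
# no malignant cell by time t. Backwards in s it satisfies the Riccati
# equation Phi_s = -(alpha Phi^2 - (alpha+beta+mu) Phi + beta) with
# Phi(t, t) = 1. With constant parameters and roots r1 < 1 < r2 of
# alpha x^2 - (alpha+beta+mu) x + beta, the Moebius substitution
# w = (Phi - r1)/(Phi - r2) linearizes it: w(u) = w0 exp(-sq u) over backward
# time u, where sq = alpha (r2 - r1). The cumulative hazard is
# H(t) = integral nu (1 - Phi) ds, and the hazard needs
# Psi = dPhi/dt, which solves a linear equation with the closed-form
# integrating factor (Phi - r1)(Phi - r2). All three propagate across a
# segment in closed form; a smoking history contributes at most three
# segments (pre-initiation, smoking, post-cessation).


def _roots(alpha, beta, mu):
    s = alpha + beta + mu
    disc = s * s - 4.0 * alpha * beta
    sq = np.sqrt(np.maximum(disc, 0.0))
    r1 = (s - sq) / (2.0 * alpha)
    r2 = (s + sq) / (2.0 * alpha)
    return r1, r2, sq


def _segment_step(phi, psi, L, nu, alpha, beta, mu, want_hazard: bool):
    """Propagate (Phi, Psi) backward across one constant-parameter segment of
    length L, returning updated state plus the segment's contributions to the
    cumulative hazard and (optionally) the hazard integral."""
    L = np.asarray(L, dtype=float)
    active = L > 0
    r1, r2, sq = _roots(alpha, beta, mu)
    w0 = (phi - r1) / (phi - r2)                      # <= 0
    wL = w0 * np.exp(-sq * L)
    phi_new = (r1 - r2 * wL) / (1.0 - wL)
    # integral of nu (1 - Phi) du over the segment
    dH = nu * ((1.0 - r1) * L + np.log((1.0 - wL) / (1.0 - w0)) / alpha)
    dh = 0.0
    psi_new = psi
    if want_hazard:
        k0 = w0 / (1.0 - w0) ** 2
        kL = wL / (1.0 - wL) ** 2
        iw = -(1.0 / np.where(sq > 0, sq, 1.0)) * (1.0 / (1.0 - wL) - 1.0 / (1.0 - w0))
        safe_k0 = np.where(np.abs(k0) > 0, k0, 1.0)
        dh = -nu * psi * iw / safe_k0
        psi_new = psi * kL / safe_k0
    degenerate = (np.asarray(mu) <= 0) | ~active
    phi_new = np.where(degenerate, phi, phi_new)
    psi_new = np.where(degenerate, psi, psi_new) if want_hazard else psi
    dH = np.where(degenerate, 0.0, dH)
    if want_hazard:
        dh = np.where(degenerate, 0.0, dh)
    return phi_new, psi_new, dH, dh


def _history_segments(smoking: SmokingHistory, params: TsceParams, t: float):
    """Constant-parameter segments of [0, t], earliest first:
    (start, end, nu, alpha, beta, mu)."""
    breaks = [0.0]
    for start, cpd in smoking.segments():
        if start < t:
            breaks.append(min(start, t))
    if smoking.init_age is not None and smoking.quit_age is not None \
            and smoking.quit_age < t:
        breaks.append(smoking.quit_age)
    breaks.append(t)
    breaks = sorted(set(breaks))
    segs = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        status = smoking.status_at(mid)
        dose = 0.0
        if status == "current":
            for start, cpd in smoking.segments():
                if start <= mid:
                    dose = cpd
        nu, alpha, beta, mu = params.at_dose(dose)
        segs.append((a, b, float(nu), float(alpha), float(beta), float(mu)))
    return segs


def tsce_hazard(smoking: SmokingHistory, age: float,
                params: TsceParams) -> float:
    """Exact hazard of malignant onset at ``age`` for one smoking history.

    For a lifelong never-smoker this is the background-parameter TSCE
    hazard; with constant parameters it approaches the asymptote
    ``nu * (1 - r1)`` at large age.
    """
    params.validate()
    if age < 0:
        raise ValueError("age must be non-negative")
    if age == 0:
        return 0.0
    segs = _history_segments(smoking, params, float(age))
    if all(seg[5] == 0 for seg in segs):
        return 0.0
    phi = 1.0
    psi = -segs[-1][5]        # dPhi/dt at s = t equals -mu(t)
    h = 0.0
    for a, b, nu, alpha, beta, mu in reversed(segs):
        phi, psi, _, dh = _segment_step(phi, psi, b - a, nu, alpha, beta, mu,
                                        want_hazard=True)
        h += float(dh)
    return h


def tsce_cumulative_hazard(smoking: SmokingHistory, age: float,
                           params: TsceParams) -> float:
    """Exact cumulative hazard of malignant onset by ``age``."""
    params.validate()
    if age <= 0:
        return 0.0
    segs = _history_segments(smoking, params, float(age))
    phi = 1.0
    H = 0.0
    for a, b, nu, alpha, beta, mu in reversed(segs):
        phi, _, dH, _ = _segment_step(phi, None, b - a, nu, alpha, beta, mu,
                                      want_hazard=False)
        H += float(dH)
    return H


def tsce_asymptotic_hazard(params: TsceParams, cpd: float = 0.0) -> float:
    """Constant-parameter large-age hazard limit, nu (1 - r1)."""
    nu, alpha, beta, mu = params.at_dose(cpd)
    r1, _, _ = _roots(float(alpha), float(beta), float(mu))
    return float(nu) * (1.0 - r1)


def _cumhaz_grid(cohort: Cohort, params: TsceParams,
                 grid: np.ndarray) -> np.ndarray:
    """(n, len(grid)) cumulative onset hazard at each grid age, vectorized.

    Each person contributes at most three segments: background before
    initiation, dosed while smoking, background after cessation.
    """
    n = cohort.n
    init = np.where(np.isnan(cohort.init_age), np.inf, cohort.init_age)
    quit = np.where(np.isnan(cohort.quit_age), np.inf, cohort.quit_age)
    nu0, a0, b0, m0 = (float(x) for x in params.at_dose(0.0))
    nu_d, a_d, b_d, m_d = params.at_dose(cohort.cpd)
    H = np.empty((n, grid.size))
    for j, t in enumerate(grid):
        lo = np.minimum(init, t)
        hi = np.minimum(quit, t)
        phi = np.ones(n)
        Ht = np.zeros(n)
        # backward: post-cessation background, smoking, pre-initiation
        phi, _, dH, _ = _segment_step(phi, None, t - hi, nu0, a0, b0, m0, False)
        Ht += dH
        phi, _, dH, _ = _segment_step(phi, None, hi - lo, nu_d, a_d, b_d, m_d, False)
        Ht += dH
        phi, _, dH, _ = _segment_step(phi, None, lo, nu0, a0, b0, m0, False)
        Ht += dH
        H[:, j] = Ht
    return H


# ---------------------------------------------------------------------------
# Disease course
# ---------------------------------------------------------------------------


@dataclass
class DiseaseArrays:
    """Latent disease course for a whole cohort under one model variant.

    All ages in years; +inf encodes "never happens". The screening overlay
    never mutates these arrays — each scenario re-derives its outcome from
    them plus the shared per-person random draws, which is what makes
    between-scenario comparisons free of Monte-Carlo noise.
    """

    onset_age: np.ndarray          # first surviving malignant cell
    histology: np.ndarray          # int8, NSCLC/SCLC
    growth_rate: np.ndarray        # diameter e-folding rate /yr
    t1mm: np.ndarray               # onset + lag: tumor reaches 1 mm
    clinical_dx_age: np.ndarray    # symptomatic diagnosis age
    dx_diameter: np.ndarray        # mm at clinical diagnosis
    stage_threshold: np.ndarray    # mm; late stage once diameter >= this
    stage_clinical: np.ndarray     # int8 EARLY/LATE at clinical diagnosis
    u_cure: np.ndarray             # shared cure uniform (both modes)
    cured_clinical: np.ndarray     # bool
    lc_death_clinical: np.ndarray  # lung-cancer death age absent screening
    variant: ModelVariant = None

    @property
    def n(self) -> int:
        return self.onset_age.shape[0]


def simulate_disease_cohort(cohort: Cohort, variant: ModelVariant,
                            seed: int) -> DiseaseArrays:
    """Simulate every person's latent disease course under ``variant``.

    Onset is sampled by inverting the exact TSCE cumulative hazard on a
    half-year age grid, conditional on no onset before cohort entry at age
    45 (members are assumed cancer-free at entry). Downstream draws (growth
    rate, detection, stage threshold, cure, survival) use one purpose-keyed
    stream so the whole course is reproducible per (seed, variant).
    """
    variant.validate()
    rng = _rng(seed, _STREAM_DISEASE, variant.stream_id)
    n = cohort.n
    p = variant.tsce

    grid = np.arange(ENTRY_AGE, TRUNCATION_AGE + 0.5, 0.5)
    H = _cumhaz_grid(cohort, p, grid)

    # conditional on onset > 45: shift the exponential target by H(45)
    e = H[:, 0] + rng.exponential(size=n)
    onset = np.full(n, np.inf)
    has = e < H[:, -1]
    idx = np.argmax(H >= e[:, None], axis=1)
    idx = np.clip(idx, 1, grid.size - 1)
    h0 = np.take_along_axis(H, (idx - 1)[:, None], axis=1)[:, 0]
    h1 = np.take_along_axis(H, idx[:, None], axis=1)[:, 0]
    frac = np.where(h1 > h0, (e - h0) / np.where(h1 > h0, h1 - h0, 1.0), 0.0)
    onset_all = grid[idx - 1] + 0.5 * np.clip(frac, 0.0, 1.0)
    onset[has] = onset_all[has]

    sclc_p = np.where(cohort.sex == MALE, variant.histology.sclc_prob_male,
                      variant.histology.sclc_prob_female)
    histology = (rng.random(n) < sclc_p).astype(np.int8)

    base_rate = np.where(histology == SCLC, variant.growth.rate_sclc,
                         variant.growth.rate_nsclc)
    growth = base_rate * np.exp(rng.normal(0.0, variant.growth.sigma, n)
                                - 0.5 * variant.growth.sigma ** 2)

    t1mm = onset + p.lag

    # clinical detection: hazard rate_at_10mm * (d/10)^power, d = exp(g u) mm
    e_det = rng.exponential(size=n)
    lam = variant.detection.rate_at_10mm
    k = variant.detection.size_power
    gk = growth * k
    u_dx = np.log1p(gk * e_det * (10.0 ** k) / lam) / gk
    clinical_dx = t1mm + u_dx
    dx_diam = np.exp(growth * u_dx)

    thresh = variant.stage.threshold_median_mm * np.exp(
        rng.normal(0.0, variant.stage.threshold_sigma, n))
    stage_clin = (dx_diam >= thresh).astype(np.int8)

    u_cure = rng.random(n)
    cure_frac = variant.survival.cure_fraction(stage_clin, MODE_CLINICAL,
                                               clinical_dx)
    cured = u_cure < cure_frac
    mean_surv = np.where(stage_clin == EARLY,
                         variant.survival.mean_survival[EARLY],
                         variant.survival.mean_survival[LATE])
    surv = rng.exponential(size=n) * mean_surv
    lc_death = np.where(cured | ~has, np.inf, clinical_dx + surv)
    clinical_dx = np.where(has, clinical_dx, np.inf)

    return DiseaseArrays(onset_age=onset, histology=histology,
                         growth_rate=growth, t1mm=t1mm,
                         clinical_dx_age=clinical_dx, dx_diameter=dx_diam,
                         stage_threshold=thresh, stage_clinical=stage_clin,
                         u_cure=u_cure, cured_clinical=cured & has,
                         lc_death_clinical=lc_death, variant=variant)


@dataclass
class DiseaseCourse:
    """Per-person latent disease course (``None`` = does not occur)."""

    onset_age: Optional[float]
    histology: Optional[int]
    clinical_dx_age: Optional[float]
    stage_at_clinical_dx: Optional[int]
    lc_death_age_clinical: Optional[float]
    growth_rate: Optional[float] = None
    t1mm: Optional[float] = None
    stage_threshold: Optional[float] = None
    u_cure: Optional[float] = None

    def size_at(self, age: float) -> float:
        """Tumor diameter (mm) at ``age``; 0 before the tumor reaches 1 mm."""
        if self.t1mm is None or age < self.t1mm:
            return 0.0
        return float(np.exp(self.growth_rate * (age - self.t1mm)))


def simulate_disease(person: Person, params_or_variant,
                     survival: Optional[SurvivalModel] = None,
                     rng_or_seed: Union[int, np.random.Generator] = 0,
                     ) -> DiseaseCourse:
    """Single-person wrapper around the vectorized cohort simulation.

    Accepts either a full :class:`ModelVariant` or a :class:`TsceParams`
    plus a :class:`SurvivalModel`. ``rng_or_seed`` must be an integer seed
    to guarantee the determinism contract (same seed, same course).
    """
    from .params import CohortParams
    if isinstance(params_or_variant, ModelVariant):
        variant = params_or_variant
    else:
        variant = ModelVariant(name="adhoc", tsce=params_or_variant,
                               survival=survival or SurvivalModel())
    seed = int(rng_or_seed) if not isinstance(rng_or_seed, np.random.Generator) \
        else int(rng_or_seed.integers(2 ** 31))
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
    d = simulate_disease_cohort(cohort, variant, seed)
    if not np.isfinite(d.onset_age[0]) or d.onset_age[0] >= min(
            person.oc_death_age, TRUNCATION_AGE):
        return DiseaseCourse(None, None, None, None, None)
    lc = d.lc_death_clinical[0]
    return DiseaseCourse(
        onset_age=float(d.onset_age[0]), histology=int(d.histology[0]),
        clinical_dx_age=float(d.clinical_dx_age[0]),
        stage_at_clinical_dx=int(d.stage_clinical[0]),
        lc_death_age_clinical=None if np.isinf(lc) else float(lc),
        growth_rate=float(d.growth_rate[0]), t1mm=float(d.t1mm[0]),
        stage_threshold=float(d.stage_threshold[0]),
        u_cure=float(d.u_cure[0]))


def survival_after_dx(stage: int, mode: str, dx_age: float,
                      course: DiseaseCourse, survival: SurvivalModel,
                      ) -> Optional[float]:
    """Outcome of a diagnosis at ``dx_age`` in ``stage`` via ``mode``.

    Returns ``None`` if cured, else the lung-cancer death age — which is the
    *clinical-trajectory* death age: the death clock runs from clinical
    diagnosis, not from an earlier screen detection, so early detection
    without cure yields zero survival gain. The cure comparison reuses the
    course's shared uniform, so a mode with a higher cure fraction cures a
    superset of the people a lower one cures.
    """
    survival.validate()
    frac = float(survival.cure_fraction(stage, mode, dx_age))
    if course.u_cure is not None and course.u_cure < frac:
        return None
    return course.lc_death_age_clinical
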