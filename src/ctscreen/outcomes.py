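"""Scenario-level benefit/harm metrics, normalized per 100,000 persons.

All counts are "per person in the population" (not per person screened),
accumulated from cohort entry at age 45 and truncated at age 90: lung-cancer
deaths at or past 90 are not counted and life-years accrue only to 90.
Deaths avoided and life-years saved are differences against the no-screening
reference run on the identical cohort with common random numbers, so they
carry no between-arm Monte-Carlo noise and are non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .params import FEMALE, MALE, TRUNCATION_AGE, ENTRY_AGE
from .screening import ScenarioArrays, NO_SCREENING

PER = 100_000
SEXES = {"male": MALE, "female": FEMALE}


@dataclass
class ScenarioOutcome:
    """Per-100,000 benefit/harm summary of one scenario for one sex group."""

    scenario_label: str
    sex: str                      # "male", "female" or "combined"
    n_screens: float
    n_followups: float
    n_lc_deaths: float
    deaths_avoided: float
    life_years_saved: float
    pct_ever_screened: float
    nns: Optional[float]          # persons ever screened per death avoided

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario_label, "sex": self.sex,
            "n_screens": self.n_screens, "n_followups": self.n_followups,
            "n_lc_deaths": self.n_lc_deaths,
            "deaths_avoided": self.deaths_avoided,
            "life_years_saved": self.life_years_saved,
            "pct_ever_screened": self.pct_ever_screened,
            "nns": np.nan if self.nns is None else self.nns,
        }


def _life_years(death_age: np.ndarray) -> np.ndarray:
    return np.minimum(death_age, TRUNCATION_AGE) - ENTRY_AGE


def _lc_death_counted(arr: ScenarioArrays, oc: np.ndarray) -> np.ndarray:
    return (arr.lc_death_age < oc) & (arr.lc_death_age < TRUNCATION_AGE)


def summarize_scenario(cohort: Cohort, arr: ScenarioArrays,
                       ref: ScenarioArrays) -> list[ScenarioOutcome]:
    """Aggregate one scenario against the no-screening reference.

    Returns outcomes for males, females, and both combined; the combined
    counts are totals over the whole cohort per 100,000 (the cohort's own
    sex mix), so they equal the population-weighted blend of the per-sex
    rates exactly.
    """
    if arr.screens.shape != ref.screens.shape or ref.label != NO_SCREENING:
        raise ValueError("reference must be the no-screening run of the "
                         "identical cohort")
    oc = cohort.oc_death_age
    lc_dead = _lc_death_counted(arr, oc)
    lc_dead_ref = _lc_death_counted(ref, oc)
    ly = _life_years(arr.death_age)
    ly_ref = _life_years(ref.death_age)
    ever = arr.screens > 0

    out = []
    groups = [("male", cohort.sex == MALE), ("female", cohort.sex == FEMALE),
              ("combined", np.ones(cohort.n, dtype=bool))]
    for name, mask in groups:
        m = int(mask.sum())
        if m == 0:
            continue
        scale = PER / m
        deaths = lc_dead[mask].sum() * scale
        avoided = (lc_dead_ref[mask].sum() - lc_dead[mask].sum()) * scale
        pct = 100.0 * ever[mask].mean()
        nns = None
        if avoided > 0:
            nns = (pct / 100.0 * PER) / avoided
        out.append(ScenarioOutcome(
            scenario_label=arr.label, sex=name,
            n_screens=arr.screens[mask].sum() * scale,
            n_followups=arr.followups[mask].sum() * scale,
            n_lc_deaths=deaths, deaths_avoided=avoided,
            life_years_saved=(ly[mask] - ly_ref[mask]).sum() * scale,
            pct_ever_screened=pct, nns=nns))
    return out


def number_needed_to_screen(outcome: ScenarioOutcome) -> Optional[float]:
    """Persons ever screened per lung-cancer death avoided.

    Undefined (``None``) when no deaths are avoided.
    """
    if outcome.deaths_avoided <= 0:
        return None
    return (outcome.pct_ever_screened / 100.0 * PER) / outcome.deaths_avoided


def outcomes_table(rows: Sequence[ScenarioOutcome]) -> pd.DataFrame:
    """Long-format table: one row per scenario x sex group."""
    return pd.DataFrame([r.as_dict() for r in rows])
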