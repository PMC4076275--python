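"""Ensemble driver, consensus summary tables, and the published-table fixture.

This module glues the pipeline together: run the full scenario grid for each
shipped model variant on a common cohort, build per-variant/per-sex
frontiers, apply the consensus rule, and summarize consensus programs as
cross-variant means and SDs of the per-100,000 metrics — the same layout as
the published 41-row consensus-program table, a transcription of which ships
with the package as a plain TSV fixture for worked-example checks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, generate_cohort
from .frontier import ConsensusSet, FrontierResult, build_frontier, consensus
from .natural_history import simulate_disease_cohort
from .outcomes import ScenarioOutcome, outcomes_table, summarize_scenario
from .params import CohortParams, ModelVariant, default_variants
from .screening import (NO_SCREENING, Program, parse_label, prepare_overlay,
                        program_grid, run_scenario, NLST_PROGRAM)

FIXTURE_NAME = "table3_consensus.tsv"

_METRICS = ("pct_ever_screened", "n_screens", "deaths_avoided", "nns",
            "life_years_saved")


# ---------------------------------------------------------------------------
# Ensemble sweep
# ---------------------------------------------------------------------------


def run_variant_sweep(cohort: Cohort, variant: ModelVariant, seed: int,
                      programs: Optional[Sequence[Program]] = None,
                      include_references: bool = True,
                      candidacy_curve=None) -> pd.DataFrame:
    """All scenarios for one variant on one cohort; long-format table with
    one row per scenario x sex group, tagged with the variant name."""
    if programs is None:
        programs, _ = program_grid()
    disease = simulate_disease_cohort(cohort, variant, seed)
    overlay = prepare_overlay(cohort, disease, seed,
                              candidacy_curve=candidacy_curve)
    ref = run_scenario(overlay, None)
    rows: list[ScenarioOutcome] = []
    rows += summarize_scenario(cohort, ref, ref)
    if include_references:
        rows += summarize_scenario(cohort, run_scenario(overlay, NLST_PROGRAM),
                                   ref)
    for prog in programs:
        rows += summarize_scenario(cohort, run_scenario(overlay, prog), ref)
    df = outcomes_table(rows)
    df.insert(0, "variant", variant.name)
    return df


def run_ensemble(n: int, seed: int,
                 variants: Optional[Sequence[ModelVariant]] = None,
                 params: Optional[CohortParams] = None,
                 programs: Optional[Sequence[Program]] = None,
                 candidacy_curve=None) -> pd.DataFrame:
    """Generate one cohort and sweep every variant over the scenario grid."""
    variants = list(variants) if variants is not None else default_variants()
    cohort = generate_cohort(n, seed, params)
    return pd.concat(
        [run_variant_sweep(cohort, v, seed, programs=programs,
                           candidacy_curve=candidacy_curve)
         for v in variants],
        ignore_index=True)


def ensemble_frontiers(outcomes: pd.DataFrame, benefit: str = "deaths_avoided",
                       sexes: Sequence[str] = ("male", "female"),
                       ) -> list[FrontierResult]:
    """Per-variant, per-sex frontiers from an ensemble outcomes table.

    Reference scenarios (no screening, the NLST approximation) are not part
    of the evaluated program grid and are excluded.
    """
    results = []
    refs = {NO_SCREENING, NLST_PROGRAM.label}
    mask = ~outcomes["scenario"].isin(refs)
    for variant in outcomes["variant"].unique():
        for sex in sexes:
            sub = outcomes[mask & (outcomes["variant"] == variant)
                           & (outcomes["sex"] == sex)]
            results.append(build_frontier(
                sub["n_screens"].to_numpy(), sub[benefit].to_numpy(),
                list(sub["scenario"]), variant_id=variant, sex=sex))
    return results


def ensemble_consensus(outcomes: pd.DataFrame,
                       benefit: str = "deaths_avoided",
                       decile_cut: int = 3,
                       min_variants: int = 3) -> ConsensusSet:
    return consensus(ensemble_frontiers(outcomes, benefit=benefit),
                     decile_cut=decile_cut, min_variants=min_variants)


# ---------------------------------------------------------------------------
# Consensus summary (published-table layout)
# ---------------------------------------------------------------------------


@dataclass
class ConsensusSummaryRow:
    """Cross-variant mean (SD) of combined-sex metrics for one program.

    The NNS entry is the mean of per-variant NNS ratios, not the ratio of
    mean numerators and denominators, matching how the published table was
    constructed. SDs use the sample (n-1) convention.
    """

    label: str
    pct_ever_screened: tuple      # (mean, sd)
    n_screens: tuple
    deaths_avoided: tuple
    nns: tuple
    life_years_saved: tuple


def summarize_consensus(outcomes: pd.DataFrame,
                        consensus_set: ConsensusSet) -> pd.DataFrame:
    """One row per consensus program: cross-variant mean and SD of each
    combined-sex per-100,000 metric, sorted by percent ever screened."""
    if not consensus_set.programs:
        raise ValueError("consensus set is empty")
    sub = outcomes[(outcomes["sex"] == "combined")
                   & outcomes["scenario"].isin(consensus_set.programs)]
    rows = []
    for label, g in sub.groupby("scenario"):
        row = {"label": label}
        for metric in _METRICS:
            vals = g[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = float(np.nanmean(vals))
            row[f"{metric}_sd"] = (float(np.nanstd(vals, ddof=1))
                                   if vals.size > 1 else 0.0)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("pct_ever_screened_mean")
    return df.reset_index(drop=True)


def normalized_plot_data(outcomes: pd.DataFrame,
                         benefit: str = "deaths_avoided",
                         reference_program: str = "A45-85-10-25",
                         ) -> pd.DataFrame:
    """Frontier-plot export: per variant x sex, benefit normalized so 1.0 is
    the within-variant prediction for the most intensive program."""
    refs = {NO_SCREENING, NLST_PROGRAM.label}
    sub = outcomes[~outcomes["scenario"].isin(refs)].copy()
    out = []
    for (variant, sex), g in sub.groupby(["variant", "sex"]):
        denom = g.loc[g["scenario"] == reference_program, benefit]
        if denom.empty or denom.iloc[0] <= 0:
            raise ValueError(f"reference program {reference_program} missing "
                             f"or with zero benefit in {variant}/{sex}")
        g = g[["scenario", "n_screens", benefit]].copy()
        g["benefit_normalized"] = g[benefit] / denom.iloc[0]
        g.insert(0, "sex", sex)
        g.insert(0, "variant", variant)
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Published-table fixture
# ---------------------------------------------------------------------------


def load_table3_fixture(path=None) -> pd.DataFrame:
    """Load the packaged 41-row consensus-program summary transcription
    (or a compatible file at ``path``).

    Validates shape, labels, and cell signs; raises with row/column
    diagnostics on a malformed fixture.
    """
    if path is None:
        ref = importlib.resources.files("ctscreen.data").joinpath(FIXTURE_NAME)
        with ref.open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    expected = ["label"] + [f"{m}_{s}" for m in _METRICS for s in ("mean", "sd")]
    if list(df.columns) != expected:
        raise ValueError(f"fixture columns {list(df.columns)} != {expected}")
    if len(df) != 41:
        raise ValueError(f"fixture must have 41 rows, found {len(df)}")
    for i, label in enumerate(df["label"]):
        try:
            prog = parse_label(label)
        except ValueError as exc:
            raise ValueError(f"fixture row {i}: bad label {label!r}") from exc
        if prog.label != label:
            raise ValueError(f"fixture row {i}: label does not round-trip")
    num = df.drop(columns="label")
    bad = np.argwhere(~(num.to_numpy(dtype=float) >= 0))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"fixture row {r}, column {num.columns[c]}: "
                         "negative or non-numeric cell")
    return df
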