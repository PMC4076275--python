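# ctscreen

Microsimulation of low-dose CT lung-cancer screening policies in a single
birth cohort. The package is aimed at modelers and screening-policy analysts
who want to rank many candidate programs — not just replicate one trial arm —
by weighing lung-cancer deaths avoided against the number of CT screens
required.

## What it does

`ctscreen` simulates US men and women born in 1950 from age 45 to death or
age 90 and evaluates **576 screening programs** crossing

* frequency: annual / biennial / triennial,
* start age 45–60, stop age 75–85,
* minimum pack-years 10–40, maximum years since quitting 10–25,

plus two reference scenarios (no screening, and an NLST-like arm of three
annual screens at ages 62–64 for ≥30 pack-years and ≤15 years since
quitting). Programs are written `A55-75-30-15` = annual, ages 55–75, ≥30
pack-years, ≤15 years since quit. Eligibility is re-assessed every year
against *both* smoking criteria, so light smokers enter late and former
smokers age out.

The pieces:

1. **Synthetic cohort** — smoking life-courses (annual initiation and
   cessation opportunities, cigarettes/day fixed at initiation from a
   five-class distribution) and smoking-stratified other-cause mortality
   (current > former > never, former rates interpolated by years since
   quitting).
2. **Natural history** — malignant onset from the exact piecewise-constant
   **two-stage clonal expansion (TSCE)** hazard with smoking-dependent
   initiation, promotion, and transformation rates; exponential tumor
   growth; size-dependent clinical detection; early/late stage; and a cure
   model: a stage- and mode-specific fraction of detected cases is cured,
   while the non-cured die exactly when they would have died under clinical
   diagnosis (lead time alone buys nothing).
3. **Screening overlay** — each of the 578 scenarios is a deterministic
   overlay on the latent disease course with **common random numbers**, so
   "deaths avoided vs no screening" has no between-arm Monte-Carlo noise
   and dominance relations (annual ⊇ biennial screens, stop 85 ⊇ stop 75)
   hold exactly.
4. **Outcomes** — per-100,000 counts truncated at age 90: CT screens
   (follow-up exams tallied separately), lung-cancer deaths, deaths avoided,
   life-years saved, % ever screened, and number needed to screen (NNS).
5. **Frontier & consensus** — per variant and sex, the efficiency frontier
   (increasing concave envelope of non-dominated programs in screens ×
   benefit), vertical distance in normalized benefit units, decile ranks,
   and the consensus rule: programs in deciles 0–3 for ≥3 of the 5 shipped
   model variants, for both sexes. A secondary frontier uses life-years
   saved as the benefit.

The five shipped **model variants** (different dose–response strengths,
growth rates, cure fractions, and one stage-shift-with-age effectiveness
mechanism) emulate an ensemble of independently built models so that the
cross-model consensus machinery can be exercised end to end.

## Worked example

```python
import pandas as pd
from ctscreen import generate_cohort, default_variants
from ctscreen.reporting import (run_variant_sweep, ensemble_consensus,
                                summarize_consensus)

cohort = generate_cohort(20_000, seed=1)
outcomes = pd.concat(
    [run_variant_sweep(cohort, v, seed=1) for v in default_variants()],
    ignore_index=True)

consensus = ensemble_consensus(outcomes)   # deciles 0-3 in >=3 variants, both sexes
print(f"{len(consensus.programs)} consensus-efficient programs")

summary = summarize_consensus(outcomes, consensus)
cols = ["label", "pct_ever_screened_mean", "n_screens_mean",
        "deaths_avoided_mean", "nns_mean", "life_years_saved_mean"]
print(summary[cols].head(5).round(1).to_string(index=False))
```

prints

```
148 consensus-efficient programs
       label  pct_ever_screened_mean  n_screens_mean  deaths_avoided_mean  nns_mean  life_years_saved_mean
B60-85-40-10                    13.6         77720.0                267.0      51.2                 3124.8
B60-75-40-10                    13.6         68839.0                222.0      62.0                 2841.8
B60-80-40-10                    13.6         75874.0                258.0      53.0                 3100.3
T60-75-40-10                    13.6         49835.0                159.0      89.5                 1931.5
T60-80-40-10                    13.6         52133.0                169.0      84.2                 2001.9
```

Each row is one consensus program with the cross-variant mean of its
combined-sex metrics per 100,000 cohort members: the strictest triennial
program (`T60-75-40-10`) screens ~14% of the cohort, needs ~50,000 CT
screens, and avoids ~159 lung-cancer deaths — about 90 people must ever be
screened per death avoided — while biennial screening to age 85 roughly
trebles the benefit for modestly more screens. Annual programs with the
NLST smoking criteria but a stop age of 85 rather than 75 sit closer to
every variant's efficiency frontier, which is the qualitative conclusion
the consensus machinery is built to surface.

A command-line interface mirrors the pipeline
(`ctscreen simulate|frontier|consensus|report|check-fixture`); a
transcription of the published 41-row consensus-program summary ships with
the package (`ctscreen.load_table3_fixture()`) for worked-example checks.

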