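# Methods

This note documents the models inside `ctscreen`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would want to know about.

## Cohort and follow-up

One closed birth cohort (US, born 1950), both sexes (default 50/50),
defined as the population alive at age 45 and followed to death or age 90.
All counted events — screens, lung-cancer deaths, deaths avoided,
life-years — are truncated at age 90 and normalized per 100,000 persons
alive at 45. Life-years are person-years lived between 45 and 90.

## Smoking life-courses

Discrete annual time steps. Each person gets one initiation opportunity per
year at ages 12–30 (a hump-shaped annual probability peaking near 17;
female probabilities scaled by 0.75) and, once smoking, one cessation
opportunity per year with an age-banded probability rising from 1%/yr
before 30 to 8%/yr after 70. Cigarettes/day is drawn once at initiation
from a five-class, quintile-style distribution (5/10/20/30/40 cpd, equal
weights) and held fixed. This yields ~56% ever-smokers, ~24% of the cohort
with ≥30 pack-years by age 55, and a current/former/never mix at entry
plausible for this cohort. Pack-years accrue as (cpd/20) × years and are
additive over arbitrary interval splits; years-since-quit (YSQ) is 0 for
current smokers by convention, so a maximum-YSQ eligibility cap can never
exclude them, and undefined for never-smokers, who are never eligible.

What is *not* emulated: calendar-period effects (tax shocks, cessation
campaigns), intensity changes over a smoking career, relapse after
quitting, and covariance between smoking and other risk factors. Passing
tests therefore demonstrate internal consistency of the pipeline and
qualitative policy orderings, not fidelity to any observed cohort's
smoking microdata.

## Other-cause mortality

Never-smoker hazard is Gompertz in age (2×10⁻³/yr at 45 for males, slope
0.088/yr, female scale 0.65). Current smokers carry a relative risk by
intensity quintile (1.4–2.6). Former smokers are linearly interpolated
from their quintile's current rate back to the never rate over 15 years
since quitting — the interpolation form is this package's choice; only the
existence of interpolation is externally given. The table ends at age 110;
a person whose cumulative hazard is never exceeded dies at the terminal
age. Sampling is piecewise-constant-hazard inversion from age 45,
conditional on being alive at 45, following the person's evolving stratum.
The construction guarantees current ≥ former ≥ never hazards, hence
stochastic ordering of survival.

## Two-stage clonal expansion (TSCE) onset model

Normal cells seed initiated clones at rate ν (clones/yr); initiated cells
divide at α, die/differentiate at β, and transform at μ per clone-year. Let
Φ(s,t) be the probability that a clone initiated at s spawns no malignant
cell by t. Backward in s, Φ satisfies the Riccati equation
Φₛ = −(αΦ² − (α+β+μ)Φ + β). With piecewise-constant parameters (constant on
each smoking segment: before initiation, while smoking, after quitting) the
Möbius substitution w = (Φ−r₁)/(Φ−r₂), with r₁ < 1 < r₂ the roots of
αx² − (α+β+μ)x + β, gives w(u) = w₀e^{−sq·u} per segment (sq = α(r₂−r₁)).
Survival, cumulative hazard H(t) = ∫ν(1−Φ)ds, and the hazard itself
(via Ψ = ∂Φ/∂t, whose linear ODE has the closed-form integrating factor
(Φ−r₁)(Φ−r₂)) all propagate across segments in closed form — no numerical
integration anywhere in the package. The test suite checks the closed form
against independent `solve_ivp` integration of the characteristic ODEs at
rtol 10⁻⁶ on 100 random histories, and against the constant-parameter
asymptote ν(1−r₁).

Dose response: while smoking d cigarettes/day, ν and μ are multiplied by
1 + c·d/20 (c = 1.0 each) and the net growth α−β by 1 + 1.3·d/20 with α
held fixed. Defaults ν = 1.75, α = 3.0, β = 2.95, μ = 10⁻⁷. The slow
background net growth (0.05/yr) keeps the never-smoker hazard rising
through old age — the steep age–incidence curve that makes screening past
75 worthwhile — instead of plateauing in midlife.

Onset is sampled by inverting the exact cumulative hazard on a half-year
age grid (linear interpolation between grid points), conditional on no
onset before cohort entry at 45; entrants are assumed cancer-free. μ = 0
degenerates cleanly to zero hazard.

## Tumor growth, detection, stage, survival

After onset, a fixed 2-year lag brings the tumor to 1 mm diameter; it then
grows exponentially at a person-level lognormal rate (median 1.05/yr
non-small-cell, 2.0/yr small-cell; σ = 0.3; small-cell probability 0.18
males / 0.14 females). Symptomatic diagnosis arrives with hazard
0.10/yr × (d/10 mm)², inverted in closed form; median clinical diameter
~30 mm. Stage is collapsed to early/late: late once diameter crosses a
per-person lognormal threshold (median 22 mm, σ = 0.6) — the same threshold
for screen and clinical detection, so earlier detection can only improve
the stage.

Survival uses a cure model. Detection (either mode) cures with a
stage/mode-specific probability; the non-cured die at the *clinical*
trajectory's death age (clinical diagnosis + exponential survival, mean
3.5 y early / 1.3 y late), so lead time without cure confers exactly zero
benefit. One shared uniform per person is compared against the applicable
cure fraction in every scenario; because the screen fractions dominate the
clinical ones (defaults 0.41/0.035 vs 0.35/0.03) and stage is monotone in
size, the set of people cured under any screening program is a superset of
those cured clinically — deaths avoided are non-negative person by person,
and equalizing all cure fractions reproduces no-screening mortality
exactly (the lead-time null test). The alternative *stage-shift* mechanism
makes cure depend on stage only (same in both modes) times a
non-increasing age-at-diagnosis factor, so benefit arises purely from
catching tumors earlier and younger.

## Screening overlay

CT sensitivity is logistic in diameter (midpoint 7.5 mm, width 2 mm,
ceiling 0.91) above a hard 2 mm floor. The latent course is simulated once
per (cohort, variant); every scenario then replays the same per-person,
per-age uniforms for detection, follow-up, and cure (common random
numbers). At each candidate age (start, start+f, …, ≤ stop) a person is
screened iff alive, undiagnosed, not previously screen-detected, and
eligible that year; adherence is perfect. Follow-up exams are tallied
separately from screens: a drawn count per true-positive pathway and, for
23% of negative screens, a small false-positive workup — approximating a
~24% positive-screen rate per round. An optional operative-candidacy gate
(persistent per-person draw against a non-increasing age curve) removes
non-candidates from screening permanently.

The shared-draw design makes the structural orderings exact rather than
statistical: the most inclusive annual program (A45-85-10-25) detects every
person at least as early as any other program, stop-85 programs dominate
their stop-75 counterparts, and annual dominates biennial at fixed
eligibility. At modest cohort sizes the most inclusive programs can *tie*
in total deaths avoided, in which case weak dominance removes the costlier
of the tied programs from the frontier; maximality still holds.

## Frontier, deciles, consensus

Within a variant × sex, each program is a point (CT screens, benefit per
100,000), benefit normalized by the maximum across programs so distances
are invariant to rescaling. Dominated points (another program with ≤
screens and ≥ benefit, one strict) are removed; the frontier is the
increasing concave envelope of the remainder anchored at the origin, and
interior points of the envelope are removed as extended dominance. Distance
from the frontier is the vertical gap to the envelope interpolated at the
program's screen count — chosen for transparency and order-invariance; the
anchoring at zero benefit means only *positive scalings* (not general
affine maps) of the benefit axis leave the geometry unchanged. Non-frontier
programs are sorted by (distance, label) and cut into ten equal-count
deciles (earlier bins take the remainder; ties broken by label so results
are deterministic). Consensus: decile ≤ 3 (frontier = decile 0 included) in
at least 3 of 5 variants, separately for males and females, intersected.
The secondary analysis swaps life-years saved onto the benefit axis.

## The five shipped variants

V1 is the calibrated central parameterization. V2 (aggressive) has faster
growth, stronger transformation dose response, lower cures; V3 (indolent)
the reverse; V4 shifts the dose response toward initiation/promotion and
uses a less sensitive scanner; V5 uses the stage-shift-with-age mechanism.
Their initiation-rate multipliers (1.10, 0.90, 0.82, 1.08 relative to V1)
spread no-screening mortality over roughly 2,200–4,400 per 100,000
(ensemble mean ≈ 3,700, SD ≈ 900). They are this package's own constructs:
an ensemble to exercise the consensus machinery, not reproductions of any
external model.

## Calibration

`scripts/calibrate.py` fixes the only free scale: ν is bisected so the
central variant's no-screening scenario yields ≈ 3,719 lifetime lung-cancer
deaths per 100,000 at n = 100,000 (the cross-model mean this pipeline is
anchored to; the cross-model SD of 820 bounds acceptable drift). Dose
coefficients and effectiveness parameters were chosen once so that heavy
continuing smokers face ~25–30% lifetime lung-cancer mortality, and the
benchmark programs' deaths avoided, NNS, and life-years land inside the
published consensus-table ranges. They are deliberately not fit to any
individual-level trial data.

## Problem sizes and numerics

Default analysis sizes: n = 100,000 for the single-scenario calibration
quantity; n = 20,000 per variant for full 578-scenario sweeps (a five-
variant sweep runs in about a minute on one core) — large enough that the
qualitative frontier conclusions are stable across seeds. Reproducibility:
every random draw comes from a purpose-keyed `SeedSequence([seed, purpose,
variant])` stream with per-person indexing, so cohorts are bit-reproducible
and scenario comparisons share draws by construction. Degenerate inputs are
handled explicitly: zero initiation probability (all never-smokers, no
screens), μ = 0 (no cancer), zero CT sensitivity (reduces exactly to no
screening), zero-hazard mortality tables (death at the table's terminal
age), empty frontier input and malformed fixtures (rejected with
diagnostics).

## Known limitations

Absolute benefit levels depend on the shipped parameterization; only the
calibration target and the qualitative orderings are anchored. No
overdiagnosis accounting, costs, radiation risk, incidental findings, or
imperfect adherence. Stage is binary and histology only modulates growth
speed and frequency. The smoking generator and mortality tables are
distributional emulations, not transcriptions of shared consortium inputs.
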