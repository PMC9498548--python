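# Methods

## Scope and model structure

`ckdflow` simulates the progression of chronic kidney disease (CKD) through
its five stages to end-stage renal disease (ESRD) in a closed population,
with healthcare disparities — "bias" — accelerating progression. It follows
the system-dynamics tradition: the state is a set of stocks (persons per
compartment), dynamics are flows (persons/year) driven by algebraic
auxiliary variables, and integration is fixed-step explicit Euler.

The compartments are

    Population → Stage1 → Stage2 → Stage3 → Stage4 → Stage5 → ESRD
                                                     ESRD → {Dialysis, Transplant, Deaths}

plus six cumulative counters (ProgressionTo2 … ProgressionToESRD,
DeathIncidence) that integrate the ladder flows; the counters are what the
headline base-vs-current overlays plot. All stocks start at zero except the
population stock, which starts at the 2020 Tennessee census count
(6,910,840). There are no births or migration, so the ten state stocks sum
to the initial population at every step — this conservation is asserted to
1e-9 relative in the tests.

## Flow equations

Incidence into stage 1 is driven by the arithmetic mean of the four risk
rates (diabetes, hypertension, diet, lifestyle; no combination rule is
standard for these, so the unweighted mean is used):

    incidence = Population · (r̄ / 100)        r̄ = (r_dia + r_htn + r_diet + r_life)/4

Progression out of stage k splits the stage into monitored and unmonitored
treatment. Bias is *cumulative*: the additive sum of patient,
primary-care-provider, nephrologist and healthcare-system components,

    B_k = b_patient,k + b_provider,k + b_neph,k + b_system,k

and the unmonitored fraction rises linearly in bias, damped by screening
(eGFR / serum-albumin testing collapsed into one coverage fraction):

    u_k = clamp(κ · B_k · (1 − c_screen), 0, 1)

Monitored patients progress at a fraction ρ of the base rate, unmonitored
at the full rate:

    progress_k = Stage_k · (p_k / 100) · [u_k + ρ·(1 − u_k)]

ESRD drains to dialysis and transplant at plain percentage rates; the death
outflow carries the same monitored/unmonitored multiplier with the
ESRD-stage bias, tying death incidence to ESRD-stage disparity. These two
functional choices (additive bias, linear-with-clamp unmonitored fraction)
are isolated behind `total_bias` and `unmonitored_fraction` so alternative
forms can be swapped without touching the model builder.

## Parameters

Units: "percentage rate" p means p/100 per year when multiplying a stock;
bias is dimensionless; fractions are in [0, 1].

| parameter | default | unit | provenance |
|---|---|---|---|
| population_init | 6,910,840 | persons | 2020 Tennessee census |
| diabetes_rate, hypertension_rate | 0.80 | %-rate/yr | study base run |
| diet_rate, lifestyle_rate | 0.80 | %-rate/yr | synthetic, set equal to the published risk rates |
| provider_bias (stages 1…5, ESRD) | 0.8, 0.08, 0.16, 0.073, 0.152, 0.33 | bias | study base run |
| patient/nephrologist/system bias | 0.05 each | bias | synthetic: small nonzero components so "cumulative" is exercised |
| base_progression_rate (stages 1…5) | 8, 7, 6, 5, 4 | %-rate/yr | synthetic: a slowly attenuating ladder, a few %/yr as in the CKD natural-history literature |
| monitored_slowdown ρ | 0.25 | fraction | synthetic: monitored care quarters the progression rate |
| screening_coverage | 0.30 | fraction | synthetic: partial eGFR/albumin screening reach |
| bias_to_unmonitored_gain κ | 0.5 | 1/bias | synthetic: base stage-1 bias (≈1) maps to ≈⅓ unmonitored |
| dialysis_rate, transplant_rate, esrd_death_rate | 40, 6, 15 | %-rate/yr | synthetic: most ESRD patients reach dialysis within ~2 years; transplant rare; high ESRD mortality |

Percentage-rate parameters are rounded to two decimal places when the
parameter set is constructed (bias levels keep their full printed precision
— the base values 0.073 and 0.152 would not survive two-decimal rounding).
The synthetic defaults were chosen once, for realism and so the base
2010–2022 run pushes nonzero flow through every compartment, and are
clearly marked in `CKDParameters`; they are model choices, not estimates of
real disparity levels.

What the synthetic configuration emulates — an empty ladder filling from an
at-risk population under constant rates — matches the study design (all
stage stocks start at zero in 2010) but not real CKD epidemiology, where
2010 prevalence was far from zero, rates drift, and patients regress,
die of other causes, and migrate. Passing tests therefore demonstrate the
mechanics and the qualitative direction of bias effects, not calibrated
Tennessee forecasts.

## Causal loop diagram

The packaged diagram encodes the social-determinants-of-health network
(poverty, employment, education, stress, housing, food and care access)
as a signed digraph. Loop polarity is mechanical: a feedback cycle is
reinforcing iff the product of its edge signs is +1. The ten labeled
loops classify as six reinforcing (R1–R6) and four balancing (B1–B4).

The source figure's individual arrow signs are not machine-readable, so
each labeled loop is encoded as an explicit signed cycle realizing its
printed R/B label while honouring the narrated causal phrases; shared
edges are sign-consistent across loops. The balancing closures through a
"Public Assistance" node (B2–B4) are a reconstruction: the narrative labels
poverty↔health feedback both reinforcing and balancing without giving the
distinguishing arrows, and a corrective public-assistance channel is the
standard way such a pair coexists. Cycles are compared up to rotation but
not reversal (direction matters in a digraph); enumeration delegates to a
length-bounded Johnson-style algorithm and is cross-checked against an
exhaustive DFS oracle in the tests.

## Numerical choices

- **Integrator**: explicit Euler, default dt = 0.0625 year. No integration
  method or time step is published for the original model; Euler is the
  classical system-dynamics default, and dt = 1/16 year keeps the decade
  run at 192 steps. Endpoint error against the single-stock exponential
  closed form is ≈0.1% at dt = 1/64 and halves when dt halves (first
  order), which bounds the discretization error of the slow CKD rates
  well below any quantity of interest.
- **Negative-stock protection**: if a stock's total outflow demand over one
  step exceeds its content, all its outflows are scaled by the same factor
  so the stock lands exactly on zero. Availability is the current content
  only — same-step inflows do not rescue outflows — keeping the rule local
  and order-independent. Counter stocks integrate the *realized* flow via
  mirror flows, so counters stay exact even when limiting engages.
- **Determinism**: no randomness anywhere in the engine; identical inputs
  give bitwise-identical trajectories, and CSV output uses shortest
  round-trip `repr` with a fixed decimal point and Unix newlines so
  re-running a manifest reproduces files byte for byte.
- **Calibration**: single-parameter bisection on a monotone endpoint
  (monotonicity is verified at the bracket ends; an out-of-range target
  raises with the achievable interval). Termination on endpoint tolerance
  or bracket width 1e-9. Only continuously stored parameters (bias levels,
  fractions) can be recovered to better than the two-decimal grid;
  percentage-rate parameters plateau at their storage resolution.
- **Scenario semantics**: overrides are whole-run constants; the study
  compares whole-run base vs. altered simulations, not mid-run switches.

## Problem sizes used in tests

The default suite simulates 2010–2022 at dt = 0.0625 (192 steps) for the
shared base run and dt = 0.25 (48 steps) for sweeps, monotonicity grids
(five points per bias component) and the twenty calibration recoveries;
cycle-enumeration equivalence uses 200 random signed digraphs of up to 8
nodes. These sizes make the full suite run in seconds while leaving every
property at full strength.

## Known limitations

- The published headline endpoints (e.g. 1.24 M progression to stage 2 by
  2022) are not reproducible: the original model's equations, parameter
  values and solver settings are unpublished, and two of the printed
  endpoints are typographically ambiguous. They are packaged as annotated
  reference fixtures only and never used as calibration truth.
- Minority communities are represented as a single aggregate population
  stock, as in the source design; no demographic stratification.
- No CKD regression to earlier stages, comorbidity mortality outside ESRD,
  births or migration.
- Auxiliary expressions are pure arithmetic; no delays, smoothing or
  lookup tables.
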