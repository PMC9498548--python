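"""Chronic kidney disease stage-ladder model with cumulative care bias.

The model tracks a closed population (Tennessee, 6,910,840 persons at the
2020 census) through the five CKD stages to end-stage renal disease (ESRD)
and its dialysis/transplant/death outcomes over 2010–2022. Risk factors
(diabetes, hypertension, diet, lifestyle) drive incidence into stage 1;
progression from each stage is accelerated by *bias* — a dimensionless
disparity level, the additive sum of patient, primary-care-provider,
nephrologist and healthcare-system components — which raises the fraction
of patients whose treatment is unmonitored:

    unmonitored_k = clamp(kappa * bias_k * (1 - screening_coverage), 0, 1)

Unmonitored patients progress at the stage's full base rate; monitored
patients progress at a fraction ``rho`` (monitored_slowdown) of it, so each
progression flow is

    Stage_k * (base_rate_k / 100) * (unmonitored_k + rho * (1 - unmonitored_k))

Screening (eGFR and serum-albumin testing) is collapsed into a single
coverage fraction that shrinks the unmonitored pool. The functional choices
are isolated behind :func:`total_bias` and :func:`unmonitored_fraction` so
alternatives can be swapped. Parameters with percentage-rate units denote
p/100 per year and are rounded to two decimal places at construction.

All stocks start at zero except the population stock. Cumulative counters
(ProgressionTo2 … ProgressionToESRD, DeathIncidence) integrate the
progression and death flows; they are what the headline trajectories plot.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields

from .engine import (
    BOUNDARY,
    AuxiliaryDef,
    FlowDef,
    ModelSpec,
    StockDef,
    Trajectory,
)

__all__ = [
    "STAGES",
    "STATE_STOCKS",
    "COUNTER_STOCKS",
    "CKDParameters",
    "default_parameters",
    "total_bias",
    "unmonitored_fraction",
    "build_ckd_model",
    "endpoint",
    "counter_for_stage",
]

#: Disease stages carrying a bias level, in progression order.
STAGES = ("1", "2", "3", "4", "5", "esrd")

#: Conserved population compartments (no births or migration).
STATE_STOCKS = (
    "Population",
    "Stage1",
    "Stage2",
    "Stage3",
    "Stage4",
    "Stage5",
    "ESRD",
    "Dialysis",
    "Transplant",
    "Deaths",
)

#: Cumulative, non-decreasing counters of flow through the ladder.
COUNTER_STOCKS = (
    "ProgressionTo2",
    "ProgressionTo3",
    "ProgressionTo4",
    "ProgressionTo5",
    "ProgressionToESRD",
    "DeathIncidence",
)

_BIAS_COMPONENTS = ("patient_bias", "provider_bias", "nephrologist_bias", "system_bias")

# Fields in percentage-rate units (p/100 per year), stored to two decimals.
_PERCENTAGE_RATE_FIELDS = (
    "diabetes_rate",
    "hypertension_rate",
    "diet_rate",
    "lifestyle_rate",
    "base_progression_rate_1",
    "base_progression_rate_2",
    "base_progression_rate_3",
    "base_progression_rate_4",
    "base_progression_rate_5",
    "dialysis_rate",
    "transplant_rate",
    "esrd_death_rate",
)

_FRACTION_FIELDS = ("monitored_slowdown", "screening_coverage")


@dataclass(frozen=True)
class CKDParameters:
    """Every named rate of the CKD model; defaults are the base run.

    Values printed in the study design: the Tennessee population, the
    0.80 diabetes/hypertension percentage rates and the per-stage
    primary-care-provider bias levels. The remaining defaults (risk rates
    for diet and lifestyle, non-provider bias components, base progression
    rates, the bias gain ``kappa``, the monitored slowdown ``rho``,
    screening coverage and ESRD outflow rates) are synthetic, documented
    model choices set so the base run moves nonzero flow through every
    stage of the ladder within the simulation window.
    """

    population_init: float = 6_910_840.0

    # risk-factor percentage rates (per year)
    diabetes_rate: float = 0.80
    hypertension_rate: float = 0.80
    diet_rate: float = 0.80
    lifestyle_rate: float = 0.80

    # per-stage bias components (dimensionless bias units)
    patient_bias_1: float = 0.05
    provider_bias_1: float = 0.8
    nephrologist_bias_1: float = 0.05
    system_bias_1: float = 0.05
    patient_bias_2: float = 0.05
    provider_bias_2: float = 0.08
    nephrologist_bias_2: float = 0.05
    system_bias_2: float = 0.05
    patient_bias_3: float = 0.05
    provider_bias_3: float = 0.16
    nephrologist_bias_3: float = 0.05
    system_bias_3: float = 0.05
    patient_bias_4: float = 0.05
    provider_bias_4: float = 0.073
    nephrologist_bias_4: float = 0.05
    system_bias_4: float = 0.05
    patient_bias_5: float = 0.05
    provider_bias_5: float = 0.152
    nephrologist_bias_5: float = 0.05
    system_bias_5: float = 0.05
    patient_bias_esrd: float = 0.05
    provider_bias_esrd: float = 0.33
    nephrologist_bias_esrd: float = 0.05
    system_bias_esrd: float = 0.05

    # base stage-progression percentage rates (per year)
    base_progression_rate_1: float = 8.0
    base_progression_rate_2: float = 7.0
    base_progression_rate_3: float = 6.0
    base_progression_rate_4: float = 5.0
    base_progression_rate_5: float = 4.0

    # treatment-split parameters
    monitored_slowdown: float = 0.25  # rho: monitored progression multiplier
    screening_coverage: float = 0.30  # eGFR / serum-albumin detection channel
    bias_to_unmonitored_gain: float = 0.5  # kappa, 1/bias

    # ESRD outflow percentage rates (per year)
    dialysis_rate: float = 40.0
    transplant_rate: float = 6.0
    esrd_death_rate: float = 15.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)):
                raise ValueError(f"{f.name} must be numeric, got {value!r}")
            if value < 0:
                raise ValueError(f"{f.name} must be >= 0, got {value}")
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in _PERCENTAGE_RATE_FIELDS:
            object.__setattr__(self, name, round(float(getattr(self, name)), 2))

    def replace(self, **overrides: float) -> "CKDParameters":
        """New parameter set with overrides applied; names are validated."""
        valid = {f.name for f in fields(self)}
        unknown = sorted(set(overrides) - valid)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {', '.join(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def default_parameters() -> CKDParameters:
    """Base-run parameter set (population 6,910,840; risk rates 0.80)."""
    return CKDParameters()


def total_bias(stage: str, params: CKDParameters) -> float:
    """Cumulative bias of a stage: additive sum of the four components."""
    stage = str(stage).lower()
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; expected one of {STAGES}")
    return sum(getattr(params, f"{comp}_{stage}") for comp in _BIAS_COMPONENTS)


def unmonitored_fraction(bias: float, params: CKDParameters) -> float:
    """Fraction of a stage's patients whose treatment is unmonitored.

    ``clamp(kappa * bias * (1 - screening_coverage), 0, 1)``; monotone
    non-decreasing in bias. The monitored fraction is its complement.
    """
    if bias < 0:
        raise ValueError(f"bias must be >= 0, got {bias}")
    raw = params.bias_to_unmonitored_gain * bias * (1.0 - params.screening_coverage)
    return min(1.0, max(0.0, raw))


def counter_for_stage(stage: str) -> str:
    """Cumulative counter downstream of a stage's bias (DeathIncidence for ESRD)."""
    stage = str(stage).lower()
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    if stage == "esrd":
        return "DeathIncidence"
    if stage == "5":
        return "ProgressionToESRD"
    return f"ProgressionTo{int(stage) + 1}"


def _treatment_multiplier_expr(stage: str) -> str:
    # unmonitored progresses at full rate, monitored at rho of it
    u = f"unmonitored_{stage}"
    return f"({u} + monitored_slowdown * (1 - {u}))"


def build_ckd_model(params: CKDParameters) -> ModelSpec:
    """Express the CKD disparity model as a simulatable ModelSpec.

    Structure: one incidence flow Population→Stage1 driven by the mean of
    the four risk rates; five bias-modulated progression flows up the
    ladder; three ESRD outflows (dialysis and transplant at plain
    percentage rates, death modulated by ESRD-stage bias); and one
    boundary-fed mirror flow per cumulative counter.
    """
    stocks = [StockDef("Population", initial_value=params.population_init)]
    stocks += [StockDef(name) for name in STATE_STOCKS if name != "Population"]
    stocks += [StockDef(name, unit="persons (cumulative)") for name in COUNTER_STOCKS]

    auxiliaries = [
        AuxiliaryDef(
            "risk_index",
            "(diabetes_rate + hypertension_rate + diet_rate + lifestyle_rate) / 4",
            unit="percentage-rate/year",
        ),
        AuxiliaryDef("incidence_rate", "Population * risk_index / 100",
                     unit="persons/year"),
    ]
    for stage in STAGES:
        auxiliaries.append(
            AuxiliaryDef(
                f"total_bias_{stage}",
                f"patient_bias_{stage} + provider_bias_{stage} + "
                f"nephrologist_bias_{stage} + system_bias_{stage}",
                unit="bias",
            )
        )
        auxiliaries.append(
            AuxiliaryDef(
                f"unmonitored_{stage}",
                f"clamp(bias_to_unmonitored_gain * total_bias_{stage} * "
                f"(1 - screening_coverage), 0, 1)",
                unit="fraction",
            )
        )

    ladder = ("Stage1", "Stage2", "Stage3", "Stage4", "Stage5", "ESRD")
    for k in range(1, 6):
        auxiliaries.append(
            AuxiliaryDef(
                f"progression_rate_{k}",
                f"Stage{k} * (base_progression_rate_{k} / 100) * "
                + _treatment_multiplier_expr(str(k)),
                unit="persons/year",
            )
        )
    auxiliaries += [
        AuxiliaryDef("dialysis_uptake_rate", "ESRD * dialysis_rate / 100",
                     unit="persons/year"),
        AuxiliaryDef("transplant_uptake_rate", "ESRD * transplant_rate / 100",
                     unit="persons/year"),
        AuxiliaryDef(
            "esrd_death_flow_rate",
            "ESRD * (esrd_death_rate / 100) * " + _treatment_multiplier_expr("esrd"),
            unit="persons/year",
        ),
    ]

    flows = [FlowDef("incidence", "Population", "Stage1", "incidence_rate")]
    for k in range(1, 6):
        flows.append(
            FlowDef(f"progress_{k}", ladder[k - 1], ladder[k], f"progression_rate_{k}")
        )
    flows += [
        FlowDef("dialysis_uptake", "ESRD", "Dialysis", "dialysis_uptake_rate"),
        FlowDef("transplant_uptake", "ESRD", "Transplant", "transplant_uptake_rate"),
        FlowDef("esrd_death", "ESRD", "Deaths", "esrd_death_flow_rate"),
    ]
    # counters integrate the realized progression/death flows
    for k in range(1, 6):
        counter = counter_for_stage(str(k))
        flows.append(
            FlowDef(f"count_{counter}", BOUNDARY, counter, mirrors=f"progress_{k}")
        )
    flows.append(FlowDef("count_DeathIncidence", BOUNDARY, "DeathIncidence",
                         mirrors="esrd_death"))

    return ModelSpec(
        stocks=stocks,
        flows=flows,
        auxiliaries=auxiliaries,
        parameters=params.as_dict(),
    )


def endpoint(traj: Trajectory, series: str, year: float) -> float:
    """Value of a series at a grid year (counters read cumulative totals)."""
    return traj.value(series, year)
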