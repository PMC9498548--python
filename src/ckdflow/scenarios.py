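"""Base-vs-current scenario runs, parameter sweeps, endpoint calibration.

A scenario is a named set of whole-run parameter overrides (no mid-run
switches): the "current" scenario raises the diabetes and hypertension
percentage rates, and each "stage-k-bias" scenario raises one stage's
primary-care-provider bias to the altered value of the study design. The
pairing of a base and an overridden trajectory on the same grid is the unit
of comparison for the headline base-vs-current overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ckd import CKDParameters, build_ckd_model, endpoint
from .engine import SimulationConfig, Trajectory, simulate

__all__ = [
    "ScenarioSpec",
    "RunPair",
    "InfeasibleTargetError",
    "paper_scenarios",
    "run_scenario",
    "run_pair",
    "dominance_check",
    "sweep",
    "calibrate_endpoint",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Named parameter overrides defining a 'current' run against the base."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)

    def apply(self, params: CKDParameters) -> CKDParameters:
        return params.replace(**self.overrides)


@dataclass
class RunPair:
    """Base and scenario trajectories simulated on identical grids."""

    base: Trajectory
    scenario: Trajectory
    config: SimulationConfig
    base_params: CKDParameters
    scenario_params: CKDParameters
    name: str = ""


def paper_scenarios() -> list[ScenarioSpec]:
    """The packaged altered-rate scenarios of the study design.

    "current" raises the diabetes (0.80→1.15) and hypertension (0.80→1.25)
    percentage rates; each bias scenario raises one stage's provider bias
    to its altered level.
    """
    return [
        ScenarioSpec("current", {"diabetes_rate": 1.15, "hypertension_rate": 1.25}),
        ScenarioSpec("stage1-bias", {"provider_bias_1": 1.3}),
        ScenarioSpec("stage2-bias", {"provider_bias_2": 1.55}),
        ScenarioSpec("stage3-bias", {"provider_bias_3": 1.32}),
        ScenarioSpec("stage4-bias", {"provider_bias_4": 1.151}),
        ScenarioSpec("stage5-bias", {"provider_bias_5": 0.275}),
        ScenarioSpec("esrd-bias", {"provider_bias_esrd": 0.72}),
    ]


def scenario_by_name(name: str) -> ScenarioSpec:
    for spec in paper_scenarios():
        if spec.name == name:
            return spec
    known = ", ".join(s.name for s in paper_scenarios())
    raise KeyError(f"unknown scenario {name!r}; packaged scenarios: {known}")


def run_scenario(
    params: CKDParameters, overrides: dict[str, float], config: SimulationConfig
) -> Trajectory:
    """Simulate the CKD model with overrides applied for the whole run."""
    return simulate(build_ckd_model(params.replace(**overrides)), config)


def run_pair(
    params: CKDParameters, scenario: ScenarioSpec, config: SimulationConfig
) -> RunPair:
    """Base and scenario runs on one grid; the input params are not mutated."""
    scenario_params = scenario.apply(params)
    return RunPair(
        base=simulate(build_ckd_model(params), config),
        scenario=simulate(build_ckd_model(scenario_params), config),
        config=config,
        base_params=params,
        scenario_params=scenario_params,
        name=scenario.name,
    )


def dominance_check(
    pair: RunPair, series: str, rtol: float = 1e-12
) -> tuple[bool, float | None]:
    """Whether the scenario series ≥ base series at every grid point.

    Returns ``(True, None)`` on dominance, else ``(False, t)`` with the
    first violating time. A relative tolerance absorbs floating-point noise.
    """
    for traj in (pair.base, pair.scenario):
        if series not in traj.series:
            raise KeyError(f"series {series!r} missing from trajectory")
    base = pair.base.series[series]
    scen = pair.scenario.series[series]
    slack = rtol * (abs(base) + 1.0)
    violations = scen < base - slack
    if violations.any():
        first = int(violations.argmax())
        return False, float(pair.base.times[first])
    return True, None


def sweep(
    params: CKDParameters,
    parameter: str,
    values,
    config: SimulationConfig,
    series: str,
    year: float,
) -> pd.DataFrame:
    """Endpoint of ``series`` at ``year`` for each value of one parameter."""
    rows = []
    for value in values:
        traj = run_scenario(params, {parameter: float(value)}, config)
        rows.append({parameter: float(value), "endpoint": endpoint(traj, series, year)})
    return pd.DataFrame(rows)


class InfeasibleTargetError(ValueError):
    """Target endpoint outside the range achievable within the bounds."""

    def __init__(self, target: float, achievable: tuple[float, float]):
        self.target = target
        self.achievable = achievable
        super().__init__(
            f"target {target} outside achievable endpoint interval "
            f"[{achievable[0]}, {achievable[1]}]"
        )


def calibrate_endpoint(
    params: CKDParameters,
    parameter: str,
    target: float,
    series: str,
    year: float,
    bounds: tuple[float, float],
    tol: float = 1e-6,
    xtol: float = 1e-9,
    config: SimulationConfig | None = None,
    max_iter: int = 200,
) -> float:
    """Fit one scalar parameter so an endpoint hits a target, by bisection.

    The endpoint must be monotone in the parameter over ``bounds`` (checked
    by evaluating both bounds) and the target must lie between the two bound
    endpoints; otherwise :class:`InfeasibleTargetError` reports the
    achievable interval. ``tol`` bounds the endpoint mismatch, ``xtol`` the
    parameter bracket width.
    """
    if config is None:
        config = SimulationConfig()
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError(f"bounds must satisfy lo < hi, got {bounds}")

    def f(x: float) -> float:
        traj = run_scenario(params, {parameter: x}, config)
        return endpoint(traj, series, year)

    f_lo, f_hi = f(lo), f(hi)
    ascending = f_hi >= f_lo
    low_end, high_end = (f_lo, f_hi) if ascending else (f_hi, f_lo)
    if not low_end - tol <= target <= high_end + tol:
        raise InfeasibleTargetError(target, (low_end, high_end))
    if abs(f_lo - target) <= tol:
        return lo
    if abs(f_hi - target) <= tol:
        return hi

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target) <= tol or (hi - lo) <= xtol:
            return mid
        if (f_mid < target) == ascending:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
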