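"""Deterministic stock-and-flow simulation engine.

The engine integrates a system-dynamics model — stocks (accumulating state
variables), flows (rates moving quantity between stocks or across the model
boundary) and auxiliaries (algebraic intermediates) — with fixed-step
explicit Euler, the classical system-dynamics default:

    S(t + dt) = S(t) + dt * (inflows(t) - outflows(t))

Stocks represent persons and must stay non-negative: if the outflow demand
of a stock in one step exceeds its current content, all of its outflows are
scaled down proportionally so the stock lands exactly on zero.

Parameters declared with percentage-rate units denote ``p/100`` per year
when multiplying a stock; they are rounded to two decimal places where the
model is built, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import expressions as xp

__all__ = [
    "BOUNDARY",
    "StockDef",
    "FlowDef",
    "AuxiliaryDef",
    "ModelSpec",
    "SimulationConfig",
    "Trajectory",
    "ValidationReport",
    "SimulationError",
    "validate_model",
    "order_auxiliaries",
    "step",
    "simulate",
    "mass_balance",
]

#: Sentinel endpoint for flows that cross the model boundary.
BOUNDARY = "BOUNDARY"


class SimulationError(RuntimeError):
    """Raised when a run cannot proceed (non-finite flow, invalid model)."""


@dataclass(frozen=True)
class StockDef:
    """An accumulating state variable (e.g. persons in CKD stage 3)."""

    name: str
    initial_value: float = 0.0
    unit: str = "persons"

    def __post_init__(self) -> None:
        if self.initial_value < 0:
            raise ValueError(f"stock {self.name!r}: initial_value must be >= 0")


@dataclass(frozen=True)
class FlowDef:
    """A rate moving quantity between stocks or across the boundary.

    ``rate_expr`` names the auxiliary whose value (persons/year) drives the
    flow. A flow with ``mirrors`` set instead realizes exactly the realized
    value of another flow each step — used for cumulative counter stocks
    that must track a flow even when negative-stock limiting rescales it.
    """

    name: str
    source: str
    sink: str
    rate_expr: str = ""
    mirrors: str | None = None


@dataclass(frozen=True)
class AuxiliaryDef:
    """An algebraic intermediate recomputed from the namespace each step."""

    name: str
    expression: str
    unit: str = "dimensionless"


@dataclass
class ModelSpec:
    """Declarative description of a simulatable stock-and-flow system."""

    stocks: list[StockDef] = field(default_factory=list)
    flows: list[FlowDef] = field(default_factory=list)
    auxiliaries: list[AuxiliaryDef] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)

    def stock_names(self) -> list[str]:
        return [s.name for s in self.stocks]

    def aux_names(self) -> list[str]:
        return [a.name for a in self.auxiliaries]


@dataclass(frozen=True)
class SimulationConfig:
    """Time window and step of a run; integration is fixed-step Euler."""

    t_start: float = 2010.0
    t_end: float = 2022.0
    dt: float = 0.0625

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = (self.t_end - self.t_start) / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(
                f"(t_end - t_start)/dt = {steps} is not a whole number of steps"
            )

    @property
    def n_steps(self) -> int:
        return round((self.t_end - self.t_start) / self.dt)

    def grid(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_steps + 1)


@dataclass
class Trajectory:
    """Time-indexed series of every stock, flow and auxiliary of a run."""

    times: np.ndarray
    series: dict[str, np.ndarray]
    kinds: dict[str, str]  # name -> "stock" | "flow" | "auxiliary"
    units: dict[str, str]

    def __post_init__(self) -> None:
        n = len(self.times)
        for name, values in self.series.items():
            if len(values) != n:
                raise ValueError(f"series {name!r} length {len(values)} != grid {n}")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.series, index=pd.Index(self.times, name="time"))

    def value(self, name: str, year: float) -> float:
        """Series value at a grid year; errors off-grid or for unknown series."""
        if name not in self.series:
            raise KeyError(f"unknown series {name!r}")
        idx = np.flatnonzero(np.isclose(self.times, year, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise ValueError(f"year {year} is not on the simulation grid")
        return float(self.series[name][idx[0]])


@dataclass
class ValidationReport:
    """Findings of :func:`validate_model`; empty findings ⇔ simulatable."""

    findings: list[tuple[str, str]] = field(default_factory=list)

    def add(self, code: str, message: str) -> None:
        self.findings.append((code, message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "model OK"
        return "\n".join(f"[{code}] {msg}" for code, msg in self.findings)


def _duplicates(names: list[str]) -> list[str]:
    seen: set[str] = set()
    dups = []
    for n in names:
        if n in seen:
            dups.append(n)
        seen.add(n)
    return dups


def _aux_dependency_graph(spec: ModelSpec) -> nx.DiGraph:
    aux_names = set(spec.aux_names())
    g = nx.DiGraph()
    g.add_nodes_from(aux_names)
    for aux in spec.auxiliaries:
        for ref in xp.referenced_names(aux.expression):
            if ref in aux_names:
                g.add_edge(ref, aux.name)  # dependency -> dependent
    return g


def validate_model(spec: ModelSpec) -> ValidationReport:
    """Collect every invariant violation; never raises."""
    report = ValidationReport()
    stock_names = spec.stock_names()
    for dup in _duplicates(stock_names):
        report.add("duplicate-stock", f"stock name {dup!r} declared more than once")
    for dup in _duplicates([f.name for f in spec.flows]):
        report.add("duplicate-flow", f"flow name {dup!r} declared more than once")
    for dup in _duplicates(spec.aux_names()):
        report.add("duplicate-aux", f"auxiliary name {dup!r} declared more than once")

    declared_stocks = set(stock_names)
    flow_names = {f.name for f in spec.flows}
    for stock in spec.stocks:
        if stock.initial_value < 0:  # defensive: StockDef also rejects this
            report.add("negative-initial", f"stock {stock.name!r} starts below zero")
    for flow in spec.flows:
        if flow.source == flow.sink:
            report.add("self-flow", f"flow {flow.name!r} has identical source and sink")
        for end, label in ((flow.source, "source"), (flow.sink, "sink")):
            if end != BOUNDARY and end not in declared_stocks:
                report.add(
                    "dangling-endpoint",
                    f"flow {flow.name!r} {label} {end!r} names no declared stock",
                )
        if flow.mirrors is not None:
            if flow.mirrors not in flow_names or flow.mirrors == flow.name:
                report.add(
                    "unknown-mirror",
                    f"flow {flow.name!r} mirrors unknown flow {flow.mirrors!r}",
                )
        elif not flow.rate_expr:
            report.add("missing-rate", f"flow {flow.name!r} has no rate expression")

    aux_names = set(spec.aux_names())
    known = aux_names | declared_stocks | set(spec.parameters) | {"t"}
    for aux in spec.auxiliaries:
        try:
            refs = xp.referenced_names(aux.expression)
        except xp.ExpressionError as exc:
            report.add("bad-expression", f"auxiliary {aux.name!r}: {exc}")
            continue
        for ref in sorted(refs - known):
            report.add(
                "unknown-name",
                f"auxiliary {aux.name!r} references undefined name {ref!r}",
            )
    for flow in spec.flows:
        if flow.mirrors is None and flow.rate_expr and flow.rate_expr not in aux_names:
            report.add(
                "unresolved-rate",
                f"flow {flow.name!r} rate_expr {flow.rate_expr!r} names no auxiliary",
            )

    try:
        graph = _aux_dependency_graph(spec)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = [u for u, _ in nx.find_cycle(graph)]
            report.add(
                "aux-cycle",
                "auxiliary dependencies form a cycle: " + " -> ".join(cycle + cycle[:1]),
            )
    except xp.ExpressionError:
        pass  # already reported per-auxiliary above
    return report


def order_auxiliaries(spec: ModelSpec) -> list[str]:
    """Topological evaluation order of auxiliaries; deterministic tie-break.

    Raises ``SimulationError`` naming the cycle if dependencies are cyclic.
    """
    graph = _aux_dependency_graph(spec)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = [u for u, _ in nx.find_cycle(graph)]
        raise SimulationError(
            "cyclic auxiliary dependencies: " + " -> ".join(cycle + cycle[:1])
        )
    return list(nx.lexicographical_topological_sort(graph))


class _CompiledModel:
    """Pre-compiled evaluation plan shared by step() and simulate()."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.aux_order = order_auxiliaries(spec)
        exprs = {a.name: a.expression for a in spec.auxiliaries}
        self.aux_code = [(n, xp.compile_expression(exprs[n])) for n in self.aux_order]
        self.real_flows = [f for f in spec.flows if f.mirrors is None]
        self.mirror_flows = [f for f in spec.flows if f.mirrors is not None]
        self.stock_names = spec.stock_names()

    def evaluate(self, state: dict[str, float], params: dict[str, float], t: float):
        """Auxiliary values and realized (limited) flow values at time t."""
        ns = dict(params)
        ns.update(state)
        ns["t"] = t
        for name, code in self.aux_code:
            ns[name] = xp.evaluate(code, ns)
        aux_values = {name: ns[name] for name, _ in self.aux_code}

        raw = {}
        for flow in self.real_flows:
            value = ns[flow.rate_expr]
            if not math.isfinite(value):
                raise SimulationError(f"flow {flow.name!r} is non-finite ({value})")
            raw[flow.name] = value
        return aux_values, raw

    def limit(self, raw: dict[str, float], state: dict[str, float], dt: float):
        """Scale each stock's outflows so it cannot be driven below zero."""
        demand: dict[str, float] = {}
        for flow in self.real_flows:
            if flow.source != BOUNDARY and raw[flow.name] > 0:
                demand[flow.source] = demand.get(flow.source, 0.0) + raw[flow.name]
        scale = {
            s: min(1.0, state[s] / (dt * d)) if d > 0 else 1.0
            for s, d in demand.items()
        }
        realized = {}
        for flow in self.real_flows:
            value = raw[flow.name]
            if flow.source != BOUNDARY and value > 0:
                value *= scale.get(flow.source, 1.0)
            realized[flow.name] = value
        for flow in self.mirror_flows:
            realized[flow.name] = realized[flow.mirrors]
        return realized

    def advance(self, state: dict[str, float], realized: dict[str, float], dt: float):
        net = dict.fromkeys(self.stock_names, 0.0)
        for flow in self.real_flows + self.mirror_flows:
            value = realized[flow.name]
            if flow.source != BOUNDARY:
                net[flow.source] -= value
            if flow.sink != BOUNDARY:
                net[flow.sink] += value
        return {
            s: max(0.0, state[s] + dt * net[s]) for s in self.stock_names
        }


def step(
    spec: ModelSpec,
    state: dict[str, float],
    params: dict[str, float],
    t: float,
    dt: float,
) -> dict[str, float]:
    """One Euler step; outflows proportionally limited at empty stocks."""
    model = _CompiledModel(spec)
    _, raw = model.evaluate(state, params, t)
    realized = model.limit(raw, state, dt)
    return model.advance(state, realized, dt)


def simulate(
    spec: ModelSpec,
    config: SimulationConfig,
    params: dict[str, float] | None = None,
) -> Trajectory:
    """Integrate the model over the configured grid.

    Deterministic: identical spec/config/params give bitwise-identical
    trajectories. ``params`` defaults to ``spec.parameters``; flow series
    record realized (limited) values at every grid point.
    """
    report = validate_model(spec)
    if not report.ok:
        raise SimulationError(f"model fails validation:\n{report}")
    if params is None:
        params = spec.parameters

    model = _CompiledModel(spec)
    times = config.grid()
    n = len(times)
    state = {s.name: float(s.initial_value) for s in spec.stocks}

    stock_series = {s: np.empty(n) for s in model.stock_names}
    flow_series = {f.name: np.empty(n) for f in spec.flows}
    aux_series = {a: np.empty(n) for a in model.aux_order}

    for i, t in enumerate(times):
        try:
            aux_values, raw = model.evaluate(state, params, float(t))
        except SimulationError as exc:
            raise SimulationError(f"t={t}: {exc}") from exc
        realized = model.limit(raw, state, config.dt)
        for name in model.stock_names:
            stock_series[name][i] = state[name]
        for name, value in realized.items():
            flow_series[name][i] = value
        for name, value in aux_values.items():
            aux_series[name][i] = value
        if i < n - 1:
            state = model.advance(state, realized, config.dt)

    series = {**stock_series, **flow_series, **aux_series}
    kinds = {s.name: "stock" for s in spec.stocks}
    kinds.update({f.name: "flow" for f in spec.flows})
    kinds.update({a.name: "auxiliary" for a in spec.auxiliaries})
    units = {s.name: s.unit for s in spec.stocks}
    units.update({f.name: "persons/year" for f in spec.flows})
    units.update({a.name: a.unit for a in spec.auxiliaries})
    return Trajectory(times=times, series=series, kinds=kinds, units=units)


def mass_balance(traj: Trajectory, spec: ModelSpec) -> np.ndarray:
    """Per-step relative residual Δ(total stocks) − dt·(net boundary flow).

    All residuals of a trajectory produced by :func:`simulate` are zero to
    floating-point accuracy unless negative-stock flooring truncated an
    update; the residual is scaled by the total stock mass.
    """
    stock_names = spec.stock_names()
    missing = [s for s in stock_names if s not in traj.series]
    missing += [f.name for f in spec.flows if f.name not in traj.series]
    if missing:
        raise ValueError(f"trajectory does not match spec; missing series {missing}")

    total = np.sum([traj.series[s] for s in stock_names], axis=0)
    net_boundary = np.zeros_like(total)
    for flow in spec.flows:
        if flow.source == BOUNDARY and flow.sink != BOUNDARY:
            net_boundary += traj.series[flow.name]
        elif flow.sink == BOUNDARY and flow.source != BOUNDARY:
            net_boundary -= traj.series[flow.name]

    dt = np.diff(traj.times)
    residual = np.diff(total) - dt * net_boundary[:-1]
    scale = np.maximum(np.abs(total[:-1]), 1.0)
    return residual / scale
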