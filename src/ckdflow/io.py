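"""Configuration, trajectory CSV, manifest and XMILE serialization.

Numeric output is locale-independent (decimal point, Unix newlines) and
written with shortest round-trip ``repr`` so CSV round trips are lossless
and re-runs are bit-exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import yaml

from . import __version__
from .ckd import CKDParameters, build_ckd_model, default_parameters
from .engine import BOUNDARY, ModelSpec, SimulationConfig, Trajectory, simulate
from .scenarios import ScenarioSpec

__all__ = [
    "ConfigError",
    "RunManifest",
    "read_config",
    "write_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_manifest",
    "read_manifest",
    "rerun_manifest",
    "export_xmile",
    "default_config_path",
]


class ConfigError(ValueError):
    """Schema or invariant violation in a configuration file."""


def default_config_path() -> Path:
    """The packaged base-run configuration file."""
    return Path(__file__).parent / "data" / "default_config.yaml"


_TOP_KEYS = {"parameters", "simulation", "scenarios"}
_SIM_KEYS = {"t_start", "t_end", "dt"}


def read_config(path) -> tuple[CKDParameters, SimulationConfig, list[ScenarioSpec]]:
    """Parse a YAML model/scenario configuration.

    Unknown keys are rejected with their key path; parameter and simulation
    sections may be partial (defaults fill the rest); a missing
    ``scenarios`` section yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a mapping")
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown key(s) at top level: {', '.join(unknown)}")

    param_section = raw.get("parameters", {}) or {}
    if not isinstance(param_section, dict):
        raise ConfigError("'parameters' must be a mapping")
    known = {f.name for f in fields(CKDParameters)}
    for key in param_section:
        if key not in known:
            raise ConfigError(f"unknown key: parameters.{key}")
    try:
        params = default_parameters().replace(**param_section)
    except (ValueError, KeyError) as exc:
        raise ConfigError(f"parameters: {exc}") from exc

    sim_section = raw.get("simulation", {}) or {}
    if not isinstance(sim_section, dict):
        raise ConfigError("'simulation' must be a mapping")
    for key in sim_section:
        if key not in _SIM_KEYS:
            raise ConfigError(f"unknown key: simulation.{key}")
    try:
        config = SimulationConfig(**sim_section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc

    scenarios: list[ScenarioSpec] = []
    for i, entry in enumerate(raw.get("scenarios", []) or []):
        if not isinstance(entry, dict):
            raise ConfigError(f"scenarios[{i}] must be a mapping")
        for key in entry:
            if key not in {"name", "overrides"}:
                raise ConfigError(f"unknown key: scenarios[{i}].{key}")
        name = entry.get("name")
        if not name:
            raise ConfigError(f"scenarios[{i}] needs a name")
        overrides = entry.get("overrides", {}) or {}
        for key in overrides:
            if key not in known:
                raise ConfigError(f"unknown key: scenarios[{i}].overrides.{key}")
        try:
            params.replace(**overrides)  # invariant check only
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"scenarios[{i}] ({name}): {exc}") from exc
        scenarios.append(ScenarioSpec(str(name), dict(overrides)))
    return params, config, scenarios


def write_config(
    path,
    params: CKDParameters,
    config: SimulationConfig,
    scenarios: list[ScenarioSpec] = (),
) -> None:
    doc = {
        "parameters": params.as_dict(),
        "simulation": {
            "t_start": config.t_start,
            "t_end": config.t_end,
            "dt": config.dt,
        },
    }
    if scenarios:
        doc["scenarios"] = [
            {"name": s.name, "overrides": dict(s.overrides)} for s in scenarios
        ]
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=False), newline="\n"
    )


# --- trajectory CSV ---------------------------------------------------------

_HEADER_RE = re.compile(r"^(?P<name>.+?) \[(?P<kind>[a-z]+): (?P<unit>.*)\]$")


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """One row per time point, one annotated column per series."""
    names = list(traj.series)
    header = ["time [grid: year]"] + [
        f"{n} [{traj.kinds[n]}: {traj.units[n]}]" for n in names
    ]
    lines = [",".join(header)]
    columns = [traj.times] + [traj.series[n] for n in names]
    for row in zip(*columns):
        lines.append(",".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_trajectory_csv(path) -> Trajectory:
    """Inverse of :func:`write_trajectory_csv`; lossless at full precision."""
    text = Path(path).read_text()
    lines = [ln for ln in text.split("\n") if ln]
    if not lines:
        raise ValueError(f"{path}: empty file, not a trajectory")
    header = lines[0].split(",")
    if len(lines) == 1:
        raise ValueError(f"{path}: header-only file, no data rows")
    names, kinds, units = [], {}, {}
    for cell in header[1:]:
        m = _HEADER_RE.match(cell)
        if not m:
            raise ValueError(f"{path}: malformed header cell {cell!r}")
        names.append(m["name"])
        kinds[m["name"]] = m["kind"]
        units[m["name"]] = m["unit"]
    data = np.array([[float(v) for v in ln.split(",")] for ln in lines[1:]])
    series = {name: data[:, i + 1].copy() for i, name in enumerate(names)}
    return Trajectory(times=data[:, 0].copy(), series=series, kinds=kinds, units=units)


# --- run manifest -----------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bitwise."""

    command: str
    parameters: dict[str, float]
    simulation: dict[str, float]
    scenario_name: str | None = None
    scenario_overrides: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    version: str = __version__


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(
        json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n", newline="\n"
    )


def read_manifest(path) -> RunManifest:
    return RunManifest(**json.loads(Path(path).read_text()))


def rerun_manifest(path, out_dir) -> list[Path]:
    """Re-execute a manifest; rewrites its trajectory CSVs under out_dir."""
    manifest = read_manifest(path)
    params = CKDParameters(**manifest.parameters)
    config = SimulationConfig(**manifest.simulation)
    if manifest.scenario_overrides:
        params = params.replace(**manifest.scenario_overrides)
    traj = simulate(build_ckd_model(params), config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in manifest.outputs:
        target = out_dir / Path(name).name
        write_trajectory_csv(traj, target)
        written.append(target)
    return written


# --- XMILE export -----------------------------------------------------------

_XMILE_NS = "http://docs.oasis-open.org/xmile/ns/XMILE/v1.0"


def export_xmile(
    spec: ModelSpec, config: SimulationConfig | None = None, name: str = "ckdflow model"
) -> str:
    """Serialize a ModelSpec to XMILE (OASIS system-dynamics interchange).

    Export only; import is not supported.
    """
    ET.register_namespace("", _XMILE_NS)
    root = ET.Element(f"{{{_XMILE_NS}}}xmile", version="1.0")
    header = ET.SubElement(root, f"{{{_XMILE_NS}}}header")
    ET.SubElement(header, f"{{{_XMILE_NS}}}vendor").text = "ckdflow"
    ET.SubElement(header, f"{{{_XMILE_NS}}}product", version=__version__).text = "ckdflow"
    ET.SubElement(header, f"{{{_XMILE_NS}}}name").text = name
    if config is not None:
        sim = ET.SubElement(root, f"{{{_XMILE_NS}}}sim_specs", method="euler")
        ET.SubElement(sim, f"{{{_XMILE_NS}}}start").text = repr(config.t_start)
        ET.SubElement(sim, f"{{{_XMILE_NS}}}stop").text = repr(config.t_end)
        ET.SubElement(sim, f"{{{_XMILE_NS}}}dt").text = repr(config.dt)
    model = ET.SubElement(root, f"{{{_XMILE_NS}}}model")
    variables = ET.SubElement(model, f"{{{_XMILE_NS}}}variables")

    inflows: dict[str, list[str]] = {}
    outflows: dict[str, list[str]] = {}
    for flow in spec.flows:
        if flow.sink != BOUNDARY:
            inflows.setdefault(flow.sink, []).append(flow.name)
        if flow.source != BOUNDARY:
            outflows.setdefault(flow.source, []).append(flow.name)
    for stock in spec.stocks:
        el = ET.SubElement(variables, f"{{{_XMILE_NS}}}stock", name=stock.name)
        ET.SubElement(el, f"{{{_XMILE_NS}}}eqn").text = repr(stock.initial_value)
        for fname in inflows.get(stock.name, []):
            ET.SubElement(el, f"{{{_XMILE_NS}}}inflow").text = fname
        for fname in outflows.get(stock.name, []):
            ET.SubElement(el, f"{{{_XMILE_NS}}}outflow").text = fname
        ET.SubElement(el, f"{{{_XMILE_NS}}}units").text = stock.unit
    for flow in spec.flows:
        el = ET.SubElement(variables, f"{{{_XMILE_NS}}}flow", name=flow.name)
        eqn = flow.rate_expr if flow.mirrors is None else flow.mirrors
        ET.SubElement(el, f"{{{_XMILE_NS}}}eqn").text = eqn
        ET.SubElement(el, f"{{{_XMILE_NS}}}units").text = "persons/year"
    for aux in spec.auxiliaries:
        el = ET.SubElement(variables, f"{{{_XMILE_NS}}}aux", name=aux.name)
        ET.SubElement(el, f"{{{_XMILE_NS}}}eqn").text = aux.expression
        ET.SubElement(el, f"{{{_XMILE_NS}}}units").text = aux.unit
    for pname, value in spec.parameters.items():
        el = ET.SubElement(variables, f"{{{_XMILE_NS}}}aux", name=pname)
        ET.SubElement(el, f"{{{_XMILE_NS}}}eqn").text = repr(float(value))

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"
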