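"""Declarative model files, trajectory CSV export, and run manifests.

Models serialize to a YAML document with ``metadata``, ``stocks``,
``flows``, ``auxiliaries`` and ``parameters`` sections; load -> save ->
load is the identity on the data model.  Trajectories export to CSV
with a leading ``Time`` column and one column per saved variable, named
exactly as in the model.  Every pipeline run writes a manifest (JSON)
recording the scenario, settings, levels, seeds and package version so
outputs can be reproduced bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .engine import (
    AuxiliaryDef,
    FlowDef,
    ModelSpec,
    ModelValidationError,
    ParameterSet,
    SimSettings,
    StockDef,
    Trajectory,
    validate_model,
)

__all__ = [
    "SchemaError",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "trajectory_to_csv",
    "trajectory_from_csv",
    "RunManifest",
]

_TOP_KEYS = {"metadata", "stocks", "flows", "auxiliaries", "parameters"}
_STOCK_KEYS = {"name", "initial_value", "non_negative"}
_FLOW_KEYS = {"name", "source", "sink", "rate_expr"}
_AUX_KEYS = {"name", "expr"}


class SchemaError(ValueError):
    """Carries every schema violation found, each with its location."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("model file schema errors:\n" + "\n".join(
            f"  - {v}" for v in self.violations))


def model_to_dict(spec: ModelSpec) -> dict:
    return {
        "metadata": dict(spec.metadata),
        "stocks": [
            {"name": s.name, "initial_value": s.initial_value, "non_negative": s.non_negative}
            for s in spec.stocks
        ],
        "flows": [
            {"name": f.name, "source": f.source, "sink": f.sink, "rate_expr": f.rate_expr}
            for f in spec.flows
        ],
        "auxiliaries": [{"name": a.name, "expr": a.expr} for a in spec.auxiliaries],
        "parameters": dict(spec.parameters.values),
    }


def model_from_dict(doc: dict, *, where: str = "<model>") -> ModelSpec:
    violations: list[str] = []
    if not isinstance(doc, dict):
        raise SchemaError([f"{where}: document must be a mapping"])
    for key in doc:
        if key not in _TOP_KEYS:
            violations.append(f"{where}: unknown top-level key {key!r}")

    def section(name, required_keys, optional: frozenset = frozenset()):
        items = doc.get(name, [])
        if not isinstance(items, list):
            violations.append(f"{where}.{name}: must be a list")
            return []
        out = []
        for i, item in enumerate(items):
            loc = f"{where}.{name}[{i}]"
            if not isinstance(item, dict):
                violations.append(f"{loc}: must be a mapping")
                continue
            for key in item:
                if key not in required_keys | optional:
                    violations.append(f"{loc}: unknown key {key!r}")
            missing = (required_keys - optional) - set(item)
            if missing:
                violations.append(f"{loc}: missing keys {sorted(missing)}")
                continue
            out.append(item)
        return out

    stocks = [
        StockDef(
            name=item["name"],
            initial_value=float(item["initial_value"]),
            non_negative=bool(item.get("non_negative", True)),
        )
        for item in section("stocks", _STOCK_KEYS, optional=frozenset({"non_negative"}))
    ]
    flows = [
        FlowDef(item["name"], item["source"], item["sink"], item["rate_expr"])
        for item in section("flows", _FLOW_KEYS)
    ]
    auxiliaries = [
        AuxiliaryDef(item["name"], item["expr"])
        for item in section("auxiliaries", _AUX_KEYS)
    ]
    params = doc.get("parameters", {})
    if not isinstance(params, dict):
        violations.append(f"{where}.parameters: must be a mapping")
        params = {}
    metadata = doc.get("metadata", {})
    if not isinstance(metadata, dict):
        violations.append(f"{where}.metadata: must be a mapping")
        metadata = {}
    if violations:
        raise SchemaError(violations)
    return ModelSpec(
        stocks=tuple(stocks),
        flows=tuple(flows),
        auxiliaries=tuple(auxiliaries),
        parameters=ParameterSet({k: float(v) for k, v in params.items()}),
        metadata=metadata,
    )


def load_model(path: str | Path) -> ModelSpec:
    """Load a model YAML file; parse errors carry line information and
    schema errors list every violation with its location."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError([f"{path}: parse error: {exc}"]) from exc
    spec = model_from_dict(doc, where=str(path))
    try:
        validate_model(spec)
    except ModelValidationError as exc:
        raise SchemaError(
            [f"{path}: [{i.code}] {i.message}" for i in exc.issues]) from exc
    return spec


def save_model(spec: ModelSpec, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(model_to_dict(spec), sort_keys=False, allow_unicode=True))


def trajectory_to_csv(traj: Trajectory, path: str | Path) -> None:
    """CSV with a leading ``Time`` column; deterministic float formatting
    (repr round-trips exactly) so identical runs give identical bytes."""
    names = list(traj.series)
    lines = [",".join(['"Time"'] + [f'"{n}"' for n in names])]
    for i, t in enumerate(traj.times):
        row = [repr(float(t))] + [repr(float(traj.series[n][i])) for n in names]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def trajectory_from_csv(path: str | Path) -> Trajectory:
    import pandas as pd

    frame = pd.read_csv(path)
    times = frame.pop("Time").to_numpy()
    return Trajectory(times=times, series={c: frame[c].to_numpy() for c in frame.columns})


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-identically."""

    scenario_id: str
    settings: dict
    intervention_levels: dict[str, float]
    outputs: dict[str, str]
    package_version: str
    seeds: dict[str, int] = field(default_factory=dict)
    command: str = ""

    @classmethod
    def create(
        cls,
        scenario_id: str,
        settings: SimSettings,
        intervention_levels: dict[str, float],
        outputs: dict[str, str],
        seeds: dict[str, int] | None = None,
        command: str = "",
    ) -> "RunManifest":
        from . import __version__

        return cls(
            scenario_id=scenario_id,
            settings={
                "t0": settings.t0, "tf": settings.tf, "dt": settings.dt,
                "method": settings.method, "save_every": settings.save_every,
            },
            intervention_levels=dict(intervention_levels),
            outputs=dict(outputs),
            package_version=__version__,
            seeds=dict(seeds or {}),
            command=command,
        )

    def sim_settings(self) -> SimSettings:
        return SimSettings(**self.settings)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
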