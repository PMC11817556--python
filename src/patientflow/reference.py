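"""The concrete patient-centric healthcare model and its scenarios.

Builds the ten-stock, sixteen-flow stock-and-flow model of a
patient-centric healthcare system.  Four "outcome" stocks — Patient
Engagement, Patient Satisfaction, Communication Effectiveness and
Patient Health Outcomes, all in million persons and starting at zero in
2022 — follow a saturating-adoption / growing-attrition form

    inflow  = alpha * driver * (1 - S/K) * (1 - SDOH * drag) * uplift
    outflow = delta0 * (1 + gamma * (t - 2022)) * S

which rises, peaks and then declines over the 2022-2032 horizon.
Social determinants of health (SDOH) enter as a single weighted
composite index in [0, 1] that drags on every adoption inflow.
Interventions (access to healthcare improvements, community health
education, patient-centric culture) multiply their target inflows by
``1 + gain * level`` and relax the targeted drag terms by ``1 - level``,
with levels 0.1-0.5 read as 10-50% intervention strength.

The original model's rate equations were never published; the forms
here are a documented reconstruction chosen as the simplest family that
produces all the reported qualitative trajectory features, with
per-scenario parameter files frozen by least-squares calibration
against the reported peak / terminal features (see
:mod:`patientflow.calibration`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .engine import (
    BOUNDARY,
    AuxiliaryDef,
    FlowDef,
    ModelSpec,
    ParameterSet,
    StockDef,
    validate_model,
)

__all__ = [
    "SDOH_FACTORS",
    "STOCK_NAMES",
    "FLOW_NAMES",
    "SDOHComposite",
    "InterventionSpec",
    "ScenarioConfig",
    "ReferenceModelError",
    "sdoh_index",
    "apply_intervention",
    "build_reference_model",
    "load_scenario",
    "list_scenarios",
    "intervention_catalog",
]

#: The thirteen social-determinants-of-health factors folded into the composite.
SDOH_FACTORS = (
    "Limited Access to Care",
    "Higher Poverty",
    "No Health Insurance",
    "School Segregation",
    "Increased Unemployment",
    "Low Income",
    "Increased Community Violent Crime",
    "Limited Access to Quality Food",
    "Poor Access to Healthcare",
    "Health Issues",
    "Poor Air and Water Quality",
    "Poor Communication with Healthcare Providers",
    "Limited English Proficiency",
)

#: The ten model stocks (million persons).
STOCK_NAMES = (
    "Active Patient Participation",
    "Patient Engagement",
    "Data Privacy",
    "Patient Satisfaction",
    "Communication Effectiveness",
    "Quality of Care",
    "Resources Allocation",
    "Care Coordination",
    "Patient Health Outcomes",
    "Patient Health Status",
)

#: The sixteen model flows (million persons / year).
FLOW_NAMES = (
    "Improved Engagement",
    "Satisfaction Enhancement",
    "Trust Development",
    "Satisfaction Assurance",
    "Satisfaction Feedback",
    "Enhanced Patient–Provider Communication",
    "Enhanced Patient Engagement",
    "Insightful Engagement",
    "Optimized Patient–Provider Interaction",
    "Insights for Enhanced Care",
    "Coordination Impact on Quality",
    "Treatment Quality Impacts",
    "Resource Utilization",
    "Coordinated Care Delivery",
    "Enhancement Feedback Outcome",
    "Decision-Making and Treatment",
)

#: Non-SDOH auxiliary factors.
OTHER_AUXILIARIES = (
    "Patient-Centric",
    "Patient Trust",
    "Patient Training Programs",
    "Mental Health Awareness",
    "Collaboration",
    "Comorbidities",
    "Patient-Centric Culture",
    "Data Collection",
)

#: Parameter key backing each SDOH factor auxiliary.
_SDOH_PARAM = {name: "sdoh_" + name.lower().replace(" ", "_") for name in SDOH_FACTORS}

#: Initial stock values (million persons); outcome stocks start at zero.
_INITIAL_VALUES = {
    "Active Patient Participation": 0.0,
    "Patient Engagement": 0.0,
    "Data Privacy": 0.4,
    "Patient Satisfaction": 0.0,
    "Communication Effectiveness": 0.0,
    "Quality of Care": 0.0,
    "Resources Allocation": 5.0,
    "Care Coordination": 0.0,
    "Patient Health Outcomes": 0.0,
    "Patient Health Status": 0.0,
}


class ReferenceModelError(ValueError):
    """Codes: MISSING_PARAMETER, UNKNOWN_TARGET, WEIGHT_MISMATCH,
    UNKNOWN_SCENARIO, BAD_LEVEL."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass(frozen=True)
class SDOHComposite:
    """The SDOH factors as one weighted composite.

    ``components`` maps each factor to a severity in [0, 1];
    ``weights`` (same keys, non-negative, summing to 1) express the
    relative importance of each factor.  The default weighting is
    uniform — no published weighting exists for these factors.
    """

    components: dict[str, float]
    weights: dict[str, float] | None = None

    def __post_init__(self):
        comps = dict(self.components)
        weights = (
            {k: 1.0 / len(comps) for k in comps}
            if self.weights is None
            else dict(self.weights)
        )
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", weights)
        if set(comps) != set(weights):
            raise ReferenceModelError(
                "WEIGHT_MISMATCH", "component and weight key sets differ")
        if any(w < 0 for w in weights.values()):
            raise ReferenceModelError("WEIGHT_MISMATCH", "negative weight")
        if abs(sum(weights.values()) - 1.0) > 1e-12:
            raise ReferenceModelError("WEIGHT_MISMATCH", "weights must sum to 1")

    @classmethod
    def uniform(cls, components: dict[str, float]) -> "SDOHComposite":
        return cls(components=components)


def sdoh_index(composite: SDOHComposite) -> float:
    """Weighted composite index: sum of weight_i * component_i, in [0, 1]
    whenever every component is."""
    return sum(
        composite.weights[k] * composite.components[k] for k in sorted(composite.components)
    )


@dataclass(frozen=True)
class InterventionSpec:
    """A policy lever: multiplies each target inflow by ``1 + gain*level``
    and scales each listed drag parameter by ``1 - level``."""

    name: str
    targets: tuple[str, ...]
    gain: float = 1.0
    drag_params: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "drag_params", tuple(self.drag_params))
        if self.gain < 0:
            raise ReferenceModelError("BAD_LEVEL", "gain must be non-negative")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named, frozen parameterization: parameter set plus the
    interventions active at their documented levels."""

    scenario_id: str
    parameters: ParameterSet
    active_interventions: tuple[tuple[InterventionSpec, float], ...] = ()
    sdoh_weights: dict[str, float] | None = None
    description: str = field(default="", compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "active_interventions", tuple(self.active_interventions))
        for _, level in self.active_interventions:
            if not 0.0 <= level <= 1.0:
                raise ReferenceModelError("BAD_LEVEL", f"level {level} outside [0, 1]")

    def intervention_level(self, name: str) -> float:
        for spec, level in self.active_interventions:
            if spec.name == name:
                return level
        return 0.0


def _load_wiring() -> list[dict[str, str]]:
    text = resources.files("patientflow.data").joinpath("wiring.csv").read_text()
    return list(csv.DictReader(text.splitlines()))


#: Rate expression for each flow (the reconstructed functional forms).
_RATE_EXPRS = {
    "Improved Engagement": (
        "alpha_pe * [Patient-Centric] * max(0, 1 - [Patient Engagement] / K_pe)"
        " * (1 - [Social Determinants of Health] * drag_pe)"
    ),
    "Enhanced Patient Engagement": (
        "beta_pe * [Patient Trust] * max(0, 1 - [Patient Engagement] / K_pe)"
    ),
    "Insightful Engagement": (
        "delta0_pe * (1 + gamma_pe * (time - 2022)) * [Patient Engagement]"
    ),
    "Satisfaction Enhancement": (
        "alpha_ps * [Patient Trust] * (1 + c_pe_ps * [Patient Engagement])"
        " * max(0, 1 - [Patient Satisfaction] / K_ps)"
        " * (1 - [Social Determinants of Health] * drag_ps)"
    ),
    "Satisfaction Feedback": (
        "beta_ps * [Mental Health Awareness]"
        " * max(0, 1 - [Patient Satisfaction] / K_ps)"
    ),
    "Satisfaction Assurance": (
        "delta0_ps * (1 + gamma_ps * (time - 2022)) * [Patient Satisfaction]"
    ),
    "Enhanced Patient–Provider Communication": (
        "alpha_ce * [Collaboration] * (1 + c_pe_ce * [Patient Engagement])"
        " * max(0, 1 - [Communication Effectiveness] / K_ce)"
        " * (1 - [Social Determinants of Health] * drag_ce)"
    ),
    "Optimized Patient–Provider Interaction": (
        "beta_ce * [Patient Training Programs]"
        " * max(0, 1 - [Communication Effectiveness] / K_ce)"
    ),
    "Insights for Enhanced Care": (
        "delta0_ce * (1 + gamma_ce * (time - 2022)) * [Communication Effectiveness]"
    ),
    "Decision-Making and Treatment": (
        "alpha_pho * [Data Collection]"
        " * (1 + c_ps_pho * [Patient Satisfaction]"
        " + c_ce_pho * [Communication Effectiveness])"
        " * max(0, 1 - [Patient Health Outcomes] / K_pho)"
        " * (1 - [Social Determinants of Health] * drag_pho)"
    ),
    "Enhancement Feedback Outcome": (
        "delta0_pho * (1 + gamma_pho * (time - 2022))"
        " * (1 + comorbidity_load * [Comorbidities]) * [Patient Health Outcomes]"
    ),
    "Trust Development": "trust_growth * max(0, 1 - [Data Privacy] / K_dp)",
    "Coordinated Care Delivery": "care_delivery_rate * [Patient-Centric Culture]",
    "Coordination Impact on Quality": "coord_transfer * [Care Coordination]",
    "Resource Utilization": "util_rate * [Resources Allocation]",
    "Treatment Quality Impacts": "quality_transfer * [Quality of Care]",
}

#: Expressions for the non-SDOH auxiliaries.
_AUX_EXPRS = {
    "Patient-Centric": "pc_level",
    "Patient Trust": "trust_base * (1 + trust_privacy_gain * [Data Privacy])",
    "Patient Training Programs": "training_level",
    "Mental Health Awareness": "mha_level",
    "Collaboration": "collab_level",
    "Comorbidities": "comorbidity_level",
    "Patient-Centric Culture": "pcc_level",
    "Data Collection": "datacoll_level",
}


def _sdoh_composite_expr(weights: dict[str, float] | None) -> str:
    if weights is None:
        weights = {k: 1.0 / len(SDOH_FACTORS) for k in SDOH_FACTORS}
    if set(weights) != set(SDOH_FACTORS):
        raise ReferenceModelError("WEIGHT_MISMATCH", "weights must cover every SDOH factor")
    if abs(sum(weights.values()) - 1.0) > 1e-12:
        raise ReferenceModelError("WEIGHT_MISMATCH", "weights must sum to 1")
    terms = [f"{weights[name]!r} * [{name}]" for name in SDOH_FACTORS]
    return " + ".join(terms)


def build_reference_model(scenario: ScenarioConfig) -> ModelSpec:
    """Construct the full model for a scenario.

    Returns a validated spec containing the ten stocks, the sixteen
    flows wired per the packaged wiring table, the auxiliary factors
    (the thirteen SDOH factors folded into one composite auxiliary),
    and the scenario's parameters — with the scenario's active
    interventions applied at their configured levels.

    Raises ``ReferenceModelError(MISSING_PARAMETER)`` if the scenario's
    parameter set lacks a symbol the equations reference.
    """
    stocks = tuple(
        StockDef(name=name, initial_value=_INITIAL_VALUES[name], non_negative=True)
        for name in STOCK_NAMES
    )
    wiring = {row["flow"]: row for row in _load_wiring()}
    flows = tuple(
        FlowDef(
            name=name,
            source=wiring[name]["source"],
            sink=wiring[name]["sink"],
            rate_expr=_RATE_EXPRS[name],
        )
        for name in FLOW_NAMES
    )
    auxiliaries = tuple(
        [AuxiliaryDef(name=n, expr=e) for n, e in _AUX_EXPRS.items()]
        + [AuxiliaryDef(name=n, expr=_SDOH_PARAM[n]) for n in SDOH_FACTORS]
        + [
            AuxiliaryDef(
                name="Social Determinants of Health",
                expr=_sdoh_composite_expr(scenario.sdoh_weights),
            )
        ]
    )
    spec = ModelSpec(
        stocks=stocks,
        flows=flows,
        auxiliaries=auxiliaries,
        parameters=scenario.parameters,
        metadata={
            "scenario_id": scenario.scenario_id,
            "units": {"stocks": "million persons", "flows": "million persons/year"},
            "description": scenario.description,
        },
    )
    try:
        validate_model(spec)
    except Exception as exc:  # surface missing parameters with the scenario name
        if "UNKNOWN_SYMBOL" in str(exc):
            raise ReferenceModelError(
                "MISSING_PARAMETER",
                f"scenario {scenario.scenario_id!r}: {exc}") from exc
        raise
    for intervention, level in scenario.active_interventions:
        spec = apply_intervention(spec, intervention, level)
    return spec


def apply_intervention(spec: ModelSpec, intervention: InterventionSpec, level: float) -> ModelSpec:
    """Return a new spec with the intervention applied at ``level``.

    Each target flow's rate becomes ``rate * (1 + gain*level)``; each
    listed drag parameter is scaled by ``1 - level``.  ``level`` is the
    fractional intervention strength (0.1 = 10%).  At level 0 the spec
    is returned unchanged; the input spec is never mutated.
    """
    if not 0.0 <= level <= 1.0:
        raise ReferenceModelError("BAD_LEVEL", f"level {level} outside [0, 1]")
    flow_names = set(spec.flow_names())
    for target in intervention.targets:
        if target not in flow_names:
            raise ReferenceModelError(
                "UNKNOWN_TARGET", f"intervention target {target!r} is not a model flow")
    for pname in intervention.drag_params:
        if pname not in spec.parameters.values:
            raise ReferenceModelError(
                "UNKNOWN_TARGET", f"drag parameter {pname!r} is not a model parameter")
    if level == 0.0:
        return spec

    uplift = f"(1 + {intervention.gain!r} * {level!r})"
    new_flows = tuple(
        replace(f, rate_expr=f"({f.rate_expr}) * {uplift}")
        if f.name in intervention.targets
        else f
        for f in spec.flows
    )
    new_params = spec.parameters.updated(
        **{p: spec.parameters[p] * (1.0 - level) for p in intervention.drag_params}
    )
    return replace(spec, flows=new_flows, parameters=new_params)


def intervention_catalog() -> dict[str, InterventionSpec]:
    """The modelled interventions and their default targets.

    Which flows each lever touches is not published; the defaults follow
    each intervention's name: access improvements act on the primary
    adoption inflows and relax every SDOH drag, education acts on the
    training / awareness driven secondary inflows, and culture change
    acts on the culture-driven flows.
    """
    return {
        "Access to Healthcare Improvements": InterventionSpec(
            name="Access to Healthcare Improvements",
            targets=(
                "Improved Engagement",
                "Satisfaction Enhancement",
                "Enhanced Patient–Provider Communication",
                "Decision-Making and Treatment",
            ),
            gain=1.0,
            drag_params=("drag_pe", "drag_ps", "drag_ce", "drag_pho"),
        ),
        "Community Health Education": InterventionSpec(
            name="Community Health Education",
            targets=(
                "Optimized Patient–Provider Interaction",
                "Satisfaction Feedback",
            ),
            gain=1.0,
        ),
        "Patient-Centric Culture": InterventionSpec(
            name="Patient-Centric Culture",
            targets=("Improved Engagement", "Coordinated Care Delivery"),
            gain=1.0,
        ),
    }


# ---------------------------------------------------------------------------
# packaged scenarios

_SCENARIO_IDS = (
    "baseline",
    "engagement_intervention",
    "satisfaction_intervention",
    "communication_intervention",
    "outcomes_intervention",
)


def _data_path(name: str):
    return resources.files("patientflow.data").joinpath(name)


def load_scenario(scenario: str | Path) -> ScenarioConfig:
    """Load a packaged scenario by id, or any scenario YAML by path."""
    if isinstance(scenario, str) and scenario in _SCENARIO_IDS:
        text = _data_path(f"scenario_{scenario}.yaml").read_text()
        base = _data_path("")
    else:
        path = Path(scenario)
        if not path.exists():
            raise ReferenceModelError(
                "UNKNOWN_SCENARIO",
                f"{scenario!r} is neither a packaged scenario id {_SCENARIO_IDS} nor a file")
        text = path.read_text()
        base = path.parent
    doc = yaml.safe_load(text)

    param_file = doc["parameter_file"]
    if isinstance(base, Path):
        param_text = (base / param_file).read_text()
    else:
        param_text = base.joinpath(param_file).read_text()
    params = ParameterSet({k: float(v) for k, v in yaml.safe_load(param_text).items()})

    catalog = intervention_catalog()
    active = []
    for item in doc.get("interventions", []):
        name = item["name"]
        default = catalog.get(name)
        spec = InterventionSpec(
            name=name,
            targets=tuple(item.get("targets", default.targets if default else ())),
            gain=float(item.get("gain", default.gain if default else 1.0)),
            drag_params=tuple(
                item.get("drag_params", default.drag_params if default else ())),
        )
        active.append((spec, float(item["level"])))

    weights = doc.get("sdoh_weights")
    if weights == "uniform":
        weights = None
    return ScenarioConfig(
        scenario_id=doc["scenario_id"],
        parameters=params,
        active_interventions=tuple(active),
        sdoh_weights=weights,
        description=doc.get("description", ""),
    )


def list_scenarios() -> tuple[str, ...]:
    return _SCENARIO_IDS
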