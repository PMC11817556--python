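"""Shared fixtures: small hand-built models and cached scenario runs."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings as hyp_settings

from patientflow import (
    AuxiliaryDef,
    BOUNDARY,
    FlowDef,
    ModelSpec,
    ParameterSet,
    SimSettings,
    StockDef,
    build_reference_model,
    integrate,
    load_scenario,
)

hyp_settings.register_profile("ci", derandomize=True, max_examples=50)
hyp_settings.load_profile("ci")

#: Production settings at full save resolution (every Euler step kept).
FULL_SETTINGS = SimSettings(save_every=1)

OUTCOME_STOCKS = (
    "Patient Engagement",
    "Patient Satisfaction",
    "Communication Effectiveness",
    "Patient Health Outcomes",
)


@pytest.fixture
def const_flow_spec() -> ModelSpec:
    """One stock, constant inflow 100/yr and outflow 50/yr, starting at
    1000 in 2022 — the hand-worked engagement example."""
    return ModelSpec(
        stocks=(StockDef("Patient Engagement", 1000.0),),
        flows=(
            FlowDef("engage", BOUNDARY, "Patient Engagement", "inflow"),
            FlowDef("disengage", "Patient Engagement", BOUNDARY, "outflow"),
        ),
        auxiliaries=(),
        parameters=ParameterSet({"inflow": 100.0, "outflow": 50.0}),
    )


@pytest.fixture
def chain_aux_spec() -> ModelSpec:
    """Auxiliary chain c -> b -> a (c depends on b, b on a)."""
    return ModelSpec(
        stocks=(StockDef("S", 1.0),),
        flows=(),
        auxiliaries=(
            AuxiliaryDef("c", "b + 1"),
            AuxiliaryDef("a", "[S] * 2"),
            AuxiliaryDef("b", "a + 1"),
        ),
        parameters=ParameterSet({}),
    )


@pytest.fixture(scope="session")
def baseline_scenario():
    return load_scenario("baseline")


@pytest.fixture(scope="session")
def baseline_traj(baseline_scenario):
    """Baseline run at production settings, full resolution (1281 samples)."""
    return integrate(build_reference_model(baseline_scenario), FULL_SETTINGS)


@pytest.fixture(scope="session")
def coarse_baseline_traj(baseline_scenario):
    """Baseline run saving every 16th step (81 samples); cheap for
    noise / recovery tests."""
    return integrate(
        build_reference_model(baseline_scenario), SimSettings(save_every=16))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_cycles(nodes: list[str], edges: set[tuple[str, str]]) -> set[tuple[str, ...]]:
    """Every simple directed cycle, canonicalized to start at the
    smallest node, by explicit enumeration: choose a subset, anchor it
    at its smallest member, and try every ordering of the rest."""
    found: set[tuple[str, ...]] = set()
    for size in range(2, len(nodes) + 1):
        for subset in itertools.combinations(sorted(nodes), size):
            first = subset[0]
            for rest in itertools.permutations(subset[1:]):
                cycle = (first, *rest)
                if all(
                    (cycle[i], cycle[(i + 1) % size]) in edges for i in range(size)
                ):
                    found.add(cycle)
    return found


def sign_product_polarity(signs: list[int]) -> str:
    """Loop polarity by multiplying link signs (+1 / -1)."""
    product = 1
    for s in signs:
        product *= s
    return "REINFORCING" if product > 0 else "BALANCING"
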