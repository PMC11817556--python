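"""Stock-and-flow system-dynamics core: model types, validation, forward Euler.

A model is a set of stocks (accumulating state variables), flows (rates
that move material between stocks or across the model boundary), and
auxiliaries (algebraic helper variables).  The state evolves by the
fundamental stock equation

    dS/dt = inflows(S, t) - outflows(S, t)

integrated with the explicit (forward) Euler scheme: all rates are
evaluated at the start-of-step state, then every stock is updated by
``dt * net_flow``.  Population stocks may be clamped at zero after each
update (people counts cannot go negative).

Flow rates are magnitudes and are floored at zero during evaluation;
a signed transfer is modelled as a pair of opposed flows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .expressions import TIME, CompiledExpr, ExprError, compile_expr, mangle_symbol

__all__ = [
    "BOUNDARY",
    "StockDef",
    "FlowDef",
    "AuxiliaryDef",
    "ParameterSet",
    "SimSettings",
    "ModelSpec",
    "Trajectory",
    "EvaluationPlan",
    "ValidationIssue",
    "ModelValidationError",
    "EngineError",
    "validate_model",
    "euler_step",
    "integrate",
    "closed_form_constant_flows",
]

#: Sentinel endpoint for flows entering from, or leaving to, outside the model.
BOUNDARY = "BOUNDARY"


@dataclass(frozen=True)
class StockDef:
    """An accumulating state variable.

    ``initial_value`` is in model units (million persons for the
    packaged healthcare model).  ``non_negative`` clamps the stock at 0
    after every Euler update.
    """

    name: str
    initial_value: float
    non_negative: bool = True


@dataclass(frozen=True)
class FlowDef:
    """A rate moving material from ``source`` to ``sink`` (units per year).

    Either endpoint may be :data:`BOUNDARY`.  ``rate_expr`` is an
    expression over time, stocks, auxiliaries and parameters.
    """

    name: str
    source: str
    sink: str
    rate_expr: str


@dataclass(frozen=True)
class AuxiliaryDef:
    """An algebraic variable computed from stocks, parameters, time and
    previously evaluated auxiliaries (the dependency graph must be acyclic)."""

    name: str
    expr: str


@dataclass(frozen=True)
class ParameterSet:
    """Immutable name -> value map of model constants."""

    values: dict[str, float]

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def updated(self, **changes: float) -> "ParameterSet":
        merged = dict(self.values)
        merged.update(changes)
        return ParameterSet(merged)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass(frozen=True)
class SimSettings:
    """Integration settings: horizon [t0, tf] in years, step dt, save stride."""

    t0: float = 2022.0
    tf: float = 2032.0
    dt: float = 0.0078125
    method: str = "EULER"
    save_every: int = 1

    def __post_init__(self):
        if self.tf <= self.t0:
            raise ValueError("tf must exceed t0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.method != "EULER":
            raise ValueError(f"unsupported integration method {self.method!r}")
        if self.save_every < 1:
            raise ValueError("save_every must be a positive integer")
        n = (self.tf - self.t0) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(tf - t0) must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return round((self.tf - self.t0) / self.dt)


@dataclass(frozen=True)
class ModelSpec:
    """A complete declarative stock-and-flow model."""

    stocks: tuple[StockDef, ...]
    flows: tuple[FlowDef, ...]
    auxiliaries: tuple[AuxiliaryDef, ...]
    parameters: ParameterSet
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "stocks", tuple(self.stocks))
        object.__setattr__(self, "flows", tuple(self.flows))
        object.__setattr__(self, "auxiliaries", tuple(self.auxiliaries))

    def stock_names(self) -> list[str]:
        return [s.name for s in self.stocks]

    def flow_names(self) -> list[str]:
        return [f.name for f in self.flows]

    def auxiliary_names(self) -> list[str]:
        return [a.name for a in self.auxiliaries]

    def with_parameters(self, params: ParameterSet) -> "ModelSpec":
        return replace(self, parameters=params)


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed simulated values: saved times plus one series per variable."""

    times: np.ndarray
    series: dict[str, np.ndarray]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(
            self, "series", {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        )
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, vals in self.series.items():
            if len(vals) != len(t):
                raise ValueError(f"series {name!r} length mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def to_frame(self):
        """Return a pandas DataFrame with a leading ``Time`` column."""
        import pandas as pd

        data = {"Time": self.times}
        data.update(self.series)
        return pd.DataFrame(data)

    def __eq__(self, other) -> bool:  # value equality for determinism checks
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and self.series.keys() == other.series.keys()
            and all(np.array_equal(self.series[k], other.series[k]) for k in self.series)
        )


@dataclass(frozen=True)
class ValidationIssue:
    """One model defect: a machine-readable code, a message, and the
    offending symbols (for ALGEBRAIC_LOOP, the cycle's node list)."""

    code: str
    message: str
    symbols: tuple[str, ...] = ()


class ModelValidationError(ValueError):
    """Carries every validation issue found, not just the first."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = list(issues)
        super().__init__(
            "model validation failed:\n"
            + "\n".join(f"  [{i.code}] {i.message}" for i in self.issues)
        )


class EngineError(RuntimeError):
    """Runtime integration failure (e.g. a non-finite rate), with context."""

    def __init__(self, code: str, message: str, *, flow: str | None = None,
                 step: int | None = None, time: float | None = None):
        self.code = code
        self.flow = flow
        self.step = step
        self.time = time
        super().__init__(f"[{code}] {message}")


@dataclass(frozen=True)
class EvaluationPlan:
    """Validated model: auxiliary evaluation order plus compiled expressions."""

    aux_order: tuple[str, ...]
    aux_exprs: dict[str, CompiledExpr] = field(compare=False)
    flow_exprs: dict[str, CompiledExpr] = field(compare=False)


def _compile_or_issue(kind: str, name: str, src: str, issues: list[ValidationIssue]):
    try:
        return compile_expr(src)
    except ExprError as exc:
        issues.append(
            ValidationIssue("BAD_EXPRESSION", f"{kind} {name!r}: {exc}", (name,))
        )
        return None


def validate_model(spec: ModelSpec) -> EvaluationPlan:
    """Check a model for structural defects and return its evaluation plan.

    The plan lists auxiliaries in a dependency-respecting order (each
    auxiliary depends only on earlier auxiliaries, stocks, parameters
    and time).  All violations are collected and reported together in a
    :class:`ModelValidationError`:

    - ``DUPLICATE_NAME`` — a name used by more than one stock / flow /
      auxiliary / parameter;
    - ``UNKNOWN_SYMBOL`` — an expression or flow endpoint references an
      undefined name;
    - ``ALGEBRAIC_LOOP`` — a dependency cycle among auxiliaries
      (simultaneous equations are rejected), reported with the cycle.
    """
    issues: list[ValidationIssue] = []

    stock_names = spec.stock_names()
    aux_names = spec.auxiliary_names()
    flow_names = spec.flow_names()
    param_names = list(spec.parameters.values)

    seen: set[str] = set()
    for name in stock_names + flow_names + aux_names + param_names:
        if name in seen:
            issues.append(ValidationIssue("DUPLICATE_NAME", f"name {name!r} defined more than once", (name,)))
        seen.add(name)
    if TIME in seen:
        issues.append(ValidationIssue("DUPLICATE_NAME", f"{TIME!r} is reserved for the clock", (TIME,)))

    known = set(stock_names) | set(aux_names) | set(param_names) | {TIME}

    aux_exprs: dict[str, CompiledExpr] = {}
    for aux in spec.auxiliaries:
        ce = _compile_or_issue("auxiliary", aux.name, aux.expr, issues)
        if ce is not None:
            aux_exprs[aux.name] = ce
            for sym in ce.names - known:
                issues.append(ValidationIssue(
                    "UNKNOWN_SYMBOL", f"auxiliary {aux.name!r} references undefined {sym!r}", (sym,)))

    flow_exprs: dict[str, CompiledExpr] = {}
    stock_set = set(stock_names)
    for flow in spec.flows:
        if flow.source == flow.sink:
            issues.append(ValidationIssue(
                "BAD_FLOW", f"flow {flow.name!r} has identical source and sink", (flow.name,)))
        for endpoint in (flow.source, flow.sink):
            if endpoint != BOUNDARY and endpoint not in stock_set:
                issues.append(ValidationIssue(
                    "UNKNOWN_SYMBOL",
                    f"flow {flow.name!r} endpoint {endpoint!r} is not a stock", (endpoint,)))
        ce = _compile_or_issue("flow", flow.name, flow.rate_expr, issues)
        if ce is not None:
            flow_exprs[flow.name] = ce
            for sym in ce.names - known:
                issues.append(ValidationIssue(
                    "UNKNOWN_SYMBOL", f"flow {flow.name!r} references undefined {sym!r}", (sym,)))

    # dependency order among auxiliaries (edges: dependency -> dependent)
    import networkx as nx

    dag = nx.DiGraph()
    dag.add_nodes_from(aux_exprs)
    for name, ce in aux_exprs.items():
        for dep in ce.names:
            if dep in aux_exprs:
                dag.add_edge(dep, name)
    try:
        order = tuple(nx.lexicographical_topological_sort(dag))
    except nx.NetworkXUnfeasible:
        for cycle in nx.simple_cycles(dag):
            issues.append(ValidationIssue(
                "ALGEBRAIC_LOOP",
                "auxiliaries form a simultaneous loop: " + " -> ".join(sorted(cycle)),
                tuple(sorted(cycle))))
        order = ()

    if issues:
        raise ModelValidationError(issues)
    return EvaluationPlan(aux_order=order, aux_exprs=aux_exprs, flow_exprs=flow_exprs)


class _Runner:
    """Compiled model bound to one shared mangled evaluation environment."""

    def __init__(self, spec: ModelSpec, plan: EvaluationPlan | None = None):
        self.spec = spec
        self.plan = plan if plan is not None else validate_model(spec)
        self.stock_keys = [(s.name, mangle_symbol(s.name)) for s in spec.stocks]
        self.aux_items = [
            (name, mangle_symbol(name), self.plan.aux_exprs[name])
            for name in self.plan.aux_order
        ]
        self.flow_items = [
            (f.name, self.plan.flow_exprs[f.name]) for f in spec.flows
        ]
        # per-stock signed flow incidence: stock index -> [(flow pos, sign)]
        index = {s.name: i for i, s in enumerate(spec.stocks)}
        self.incidence: list[list[tuple[int, float]]] = [[] for _ in spec.stocks]
        for j, f in enumerate(spec.flows):
            if f.source != BOUNDARY:
                self.incidence[index[f.source]].append((j, -1.0))
            if f.sink != BOUNDARY:
                self.incidence[index[f.sink]].append((j, +1.0))
        self.clamp = [s.non_negative for s in spec.stocks]
        self.env: dict[str, float] = {
            mangle_symbol(k): float(v) for k, v in spec.parameters.values.items()
        }
        self.time_key = mangle_symbol(TIME)

    def eval_algebra(self, state: list[float], t: float) -> list[float]:
        """Set state/time in the environment, evaluate auxiliaries then
        flow rates (floored at 0); returns the rate vector."""
        env = self.env
        env[self.time_key] = t
        for (_, key), value in zip(self.stock_keys, state):
            env[key] = value
        for name, key, ce in self.aux_items:
            try:
                env[key] = ce.evaluate_mangled(env)
            except ZeroDivisionError:
                raise EngineError(
                    "NONFINITE_RATE",
                    f"auxiliary {name!r} divides by zero at t={t:.6g}", time=t
                ) from None
        rates = []
        for name, ce in self.flow_items:
            try:
                r = ce.evaluate_mangled(env)
            except ZeroDivisionError:
                raise EngineError(
                    "NONFINITE_RATE",
                    f"flow {name!r} divides by zero at t={t:.6g}",
                    flow=name, time=t) from None
            if not math.isfinite(r):
                raise EngineError(
                    "NONFINITE_RATE",
                    f"flow {name!r} evaluated to {r!r} at t={t:.6g}",
                    flow=name, time=t)
            rates.append(r if r > 0.0 else 0.0)
        return rates

    def step(self, state: list[float], t: float, dt: float) -> list[float]:
        rates = self.eval_algebra(state, t)
        new = list(state)
        for i, terms in enumerate(self.incidence):
            net = 0.0
            for j, sign in terms:
                net += sign * rates[j]
            new[i] = state[i] + dt * net
            if self.clamp[i] and new[i] < 0.0:
                new[i] = 0.0
        return new


def euler_step(state: dict[str, float], spec: ModelSpec, t: float, dt: float) -> dict[str, float]:
    """One forward-Euler update of all stocks.

    Rates are evaluated at ``(t, state)``; each stock then moves by
    ``dt * (inflows - outflows)`` and non-negative stocks are clamped
    at zero.  ``state`` is not mutated.
    """
    runner = _Runner(spec)
    vec = [float(state[name]) for name, _ in runner.stock_keys]
    new = runner.step(vec, t, dt)
    return {name: v for (name, _), v in zip(runner.stock_keys, new)}


def integrate(spec: ModelSpec, settings: SimSettings) -> Trajectory:
    """Integrate a validated model with forward Euler.

    The returned trajectory holds every stock, every flow rate and every
    auxiliary at the saved times ``t0, t0 + dt*save_every, ..., tf``
    (the final time is always saved).  Identical inputs produce
    bit-identical output.
    """
    runner = _Runner(spec)
    n_steps = settings.n_steps
    dt = settings.dt

    save_steps = list(range(0, n_steps + 1, settings.save_every))
    if save_steps[-1] != n_steps:
        save_steps.append(n_steps)
    save_set = set(save_steps)

    names = (
        [name for name, _ in runner.stock_keys]
        + [name for name, _ in runner.flow_items]
        + [name for name, _, _ in runner.aux_items]
    )
    out: dict[str, list[float]] = {name: [] for name in names}
    times: list[float] = []

    state = [float(s.initial_value) for s in spec.stocks]
    for k in range(n_steps + 1):
        t = settings.t0 + k * dt
        try:
            rates = runner.eval_algebra(state, t)
        except EngineError as exc:
            raise EngineError(exc.code, f"{exc} at step {k}", flow=exc.flow,
                              step=k, time=t) from None
        if k in save_set:
            times.append(t)
            for (name, _), v in zip(runner.stock_keys, state):
                out[name].append(v)
            for (name, _), r in zip(runner.flow_items, rates):
                out[name].append(r)
            for name, key, _ in runner.aux_items:
                out[name].append(runner.env[key])
        if k == n_steps:
            break
        new = list(state)
        for i, terms in enumerate(runner.incidence):
            net = 0.0
            for j, sign in terms:
                net += sign * rates[j]
            new[i] = state[i] + dt * net
            if runner.clamp[i] and new[i] < 0.0:
                new[i] = 0.0
        state = new

    return Trajectory(times=np.array(times), series={k: np.array(v) for k, v in out.items()})


def closed_form_constant_flows(S0: float, I: float, O: float, t0: float, t: float) -> float:
    """Stock value under constant inflow ``I`` and outflow ``O``:
    ``S0 + (I - O) * (t - t0)`` — the integral form specialized to
    constant rates, for which forward Euler is exact at any step size."""
    if t < t0:
        raise ValueError("t must be >= t0")
    return S0 + (I - O) * (t - t0)
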