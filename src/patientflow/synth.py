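"""Synthetic-data stage: seeded parameter ensembles, noisy observations,
and parameter recovery.

The study design rests entirely on simulated trajectories, so the
package carries its own synthetic-data machinery: draw parameter sets
from declared ranges (independent uniform or Latin hypercube), overlay
seeded Gaussian observation noise on a simulated series, and refit
chosen parameters from the noisy series to check that the estimation
pipeline recovers the generating values.  Every stochastic operation is
a pure function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .engine import ParameterSet, SimSettings, Trajectory, integrate
from .reference import ScenarioConfig, build_reference_model

__all__ = [
    "Sampling",
    "EnsembleSpec",
    "NoisySeries",
    "RecoveryResult",
    "SynthError",
    "sample_ensemble",
    "add_observation_noise",
    "fit_constant_net_flow",
    "recover_parameters",
]


class Sampling(str, Enum):
    UNIFORM = "UNIFORM"
    LATIN_HYPERCUBE = "LATIN_HYPERCUBE"


class SynthError(ValueError):
    """Codes: EMPTY_RANGES, UNKNOWN_VARIABLE, DEGENERATE_TIMES,
    UNKNOWN_PARAMETER."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass(frozen=True)
class EnsembleSpec:
    """A seeded parameter-sampling plan over axis-aligned ranges."""

    ranges: dict[str, tuple[float, float]]
    n: int
    seed: int
    sampling: Sampling = Sampling.LATIN_HYPERCUBE

    def __post_init__(self):
        object.__setattr__(self, "ranges", dict(self.ranges))
        object.__setattr__(self, "sampling", Sampling(self.sampling))
        if not self.ranges:
            raise SynthError("EMPTY_RANGES", "at least one parameter range required")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise SynthError("EMPTY_RANGES", f"range for {name!r} must have lo < hi")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def sample_ensemble(spec: EnsembleSpec) -> list[ParameterSet]:
    """Draw ``n`` parameter sets within the declared ranges.

    UNIFORM draws each parameter independently; LATIN_HYPERCUBE
    stratifies every parameter into ``n`` equal strata with exactly one
    draw per stratum.  Identical spec (including seed) gives identical
    output.
    """
    names = sorted(spec.ranges)
    lo = np.array([spec.ranges[k][0] for k in names])
    hi = np.array([spec.ranges[k][1] for k in names])
    if spec.sampling is Sampling.UNIFORM:
        rng = np.random.default_rng(spec.seed)
        unit = rng.random((spec.n, len(names)))
    else:
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(n=spec.n)
    scaled = lo + unit * (hi - lo)
    return [ParameterSet(dict(zip(names, row))) for row in scaled.tolist()]


@dataclass(frozen=True)
class NoisySeries:
    """A simulated series with additive observation noise.

    ``sigma`` is the noise standard deviation in series units (million
    persons for the packaged model); sigma 0 reproduces the base series
    exactly, and the same seed always reproduces the same perturbation.
    """

    base: Trajectory
    variable: str
    sigma: float
    seed: int
    values: np.ndarray = field(compare=False)

    @property
    def times(self) -> np.ndarray:
        return self.base.times


def add_observation_noise(
    traj: Trajectory, variable: str, sigma: float, seed: int, *, clamp: bool = True
) -> NoisySeries:
    """Additive zero-mean Gaussian perturbation per saved sample,
    clamped at zero by default (population series stay non-negative)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if variable not in traj.series:
        raise SynthError("UNKNOWN_VARIABLE", f"no variable {variable!r}")
    base_values = traj[variable]
    if sigma == 0:
        values = base_values.copy()
    else:
        rng = np.random.default_rng(seed)
        values = base_values + rng.normal(0.0, sigma, size=base_values.shape)
        if clamp:
            values = np.maximum(values, 0.0)
    return NoisySeries(base=traj, variable=variable, sigma=sigma, seed=seed, values=values)


def fit_constant_net_flow(times, values) -> float:
    """Net flow (per year) of a series under the constant-rate stock
    model S(t) = S0 + (I - O) t: the ordinary-least-squares slope of
    value against time."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2 or values.size != times.size:
        raise SynthError("DEGENERATE_TIMES", "need >= 2 paired samples")
    if np.ptp(times) == 0:
        raise SynthError("DEGENERATE_TIMES", "all sample times identical")
    return float(stats.linregress(times, values).slope)


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a parameter-recovery fit."""

    parameters: ParameterSet
    free: tuple[str, ...]
    sse: float
    converged: bool
    n_evaluations: int


def recover_parameters(
    observed: NoisySeries,
    scenario: ScenarioConfig,
    free: list[str] | tuple[str, ...],
    settings: SimSettings | None = None,
    *,
    maxiter: int = 500,
    bounds_scale: tuple[float, float] = (0.2, 5.0),
) -> RecoveryResult:
    """Refit ``free`` parameters to a noisy observed series.

    Minimizes the sum of squared deviations between the observed values
    and the same variable simulated from the scenario's model, over the
    free parameters, using bounded Nelder-Mead started from the
    scenario defaults (bounds are ``defaults * bounds_scale``).
    Deterministic given the observed series.  With an empty ``free``
    list the defaults and their plain residual are returned.  If the
    iteration cap is reached the best point found is returned with
    ``converged=False``.
    """
    free = tuple(free)
    defaults = scenario.parameters
    for name in free:
        if name not in defaults.values:
            raise SynthError("UNKNOWN_PARAMETER", f"no parameter {name!r}")
    if settings is None:
        # infer the save stride from the observed grid; the step itself
        # stays at the scenario's integration step
        base = SimSettings()
        stride = max(1, round((observed.times[1] - observed.times[0]) / base.dt))
        settings = SimSettings(
            t0=float(observed.times[0]), tf=float(observed.times[-1]),
            dt=base.dt, save_every=stride,
        )

    target = np.asarray(observed.values, dtype=float)

    evaluations = 0

    def objective(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        params = defaults.updated(**dict(zip(free, (float(v) for v in x))))
        scen = ScenarioConfig(
            scenario_id=scenario.scenario_id,
            parameters=params,
            active_interventions=scenario.active_interventions,
            sdoh_weights=scenario.sdoh_weights,
        )
        traj = integrate(build_reference_model(scen), settings)
        sim = traj[observed.variable]
        if sim.shape != target.shape:
            raise SynthError(
                "DEGENERATE_TIMES",
                "observed grid does not match the simulation grid")
        return float(np.sum((sim - target) ** 2))

    if not free:
        sse = objective(np.empty(0))
        return RecoveryResult(
            parameters=defaults, free=free, sse=sse, converged=True,
            n_evaluations=evaluations)

    x0 = np.array([defaults[name] for name in free], dtype=float)
    bounds = [(v * bounds_scale[0], v * bounds_scale[1]) for v in x0]
    result = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": maxiter, "fatol": 1e-8, "xatol": 1e-8},
    )
    fitted = defaults.updated(**dict(zip(free, (float(v) for v in result.x))))
    return RecoveryResult(
        parameters=fitted,
        free=free,
        sse=float(result.fun),
        converged=bool(result.success),
        n_evaluations=evaluations,
    )
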