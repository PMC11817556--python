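# Methods

## Model and integration scheme

The engine integrates declarative stock-and-flow models. A model is a
set of stocks S with initial values, flows (non-negative rates in units
per year moving material between stocks or across the model boundary),
auxiliaries (algebraic variables), and scalar parameters. The state
obeys dS/dt = Σ inflows − Σ outflows, discretized by explicit (forward)
Euler: all rates are evaluated at the start-of-step state, then each
stock is updated by dt·net. Forward Euler was chosen over other
variants because it is the default in mainstream system-dynamics tools
and reproduces the arithmetic of the classic constant-flow worked
example (S(2025) = 1000 + 3·50 = 1150) exactly; for constant rates the
discrete sum telescopes to the closed form at any step size, which the
test suite exploits as an exactness oracle.

Numerical conventions:

- **Step size.** Production settings are t₀ = 2022, t_f = 2032,
  dt = 0.0078125 yr (2⁻⁷, ≈3 days, 1280 steps). dt being a binary
  fraction keeps saved times exact in floating point. `save_every`
  thins the saved grid (default pipelines keep every 16th step, 0.125 yr;
  full-resolution saving is a flag); the final time is always saved.
- **Clamping.** Stocks flagged non-negative (all population stocks) are
  floored at 0 after each update; flow rates are floored at 0 when
  evaluated (a signed transfer is modelled as a pair of opposed flows).
- **Degenerate inputs.** A rate evaluating to NaN/∞ (or dividing by
  zero) aborts the run with the flow name, step index and time.
  Validation reports *every* defect at once: duplicate names, unknown
  symbols, and algebraic loops among auxiliaries (with the cycle),
  since simultaneous equations are rejected by design.
- **Expression language.** Rates are written in a deliberately small
  arithmetic language (numbers, names, `+ − × ÷`, `min`, `max`, a
  smooth saturation `sat(x) = x/(1+|x|)`, a ramp). Multi-word variable
  names appear in square brackets (`[Patient Engagement]`). Anything
  richer is rejected at parse time, so model files cannot execute code.

## The patient-centric healthcare model

Ten stocks (million persons), sixteen flows, and auxiliary factors
including a composite social-determinants-of-health index. The exact
rate equations behind the published trajectory figures were never
released, so the packaged equations are a documented reconstruction:
the simplest family that produces every reported qualitative feature.
Each of the four outcome stocks (Patient Engagement, Patient
Satisfaction, Communication Effectiveness, Patient Health Outcomes;
all starting at 0 in 2022) has

- a saturating adoption inflow α·driver·(1 − S/K)·(1 − sdoh·drag),
  with a secondary inflow from a trust/awareness/training auxiliary;
- an attrition outflow δ(t)·S with δ(t) = δ₀·(1 + γ·(t − 2022)),
  so attrition strengthens over the decade and every outcome stock
  rises, peaks and declines;
- forward couplings: engagement enters the satisfaction and
  communication inflows, and both enter the outcomes inflow
  (coefficients c_* ≈ 0.15), forming a causal cascade.

Supporting stocks (Data Privacy, Resources Allocation, Care
Coordination, Quality of Care, Active Patient Participation, Patient
Health Status) follow simple linear transfer dynamics; they give the
model its full wiring (each of the sixteen named flows has a
name-plausible source and sink, recorded with per-row provenance in
`data/wiring.csv`) without being calibration targets.

**SDOH composite.** The thirteen SDOH factors are severities in [0, 1]
combined with non-negative weights summing to 1 (uniform by default —
no published weighting exists). The composite multiplies every primary
adoption inflow through a drag term (1 − sdoh·drag).

**Interventions.** A lever multiplies each target inflow by
(1 + gain·level) and relaxes its drag parameters by (1 − level), with
level ∈ [0, 1] read as fractional strength (0.1–0.5 = 10–50% on the
standard sweep grid). At level 0 the model is returned unchanged, which
makes the zero-level sweep bit-identical to the baseline run. Which
flows each named intervention touches is a documented modelling choice
(`intervention_catalog`): access improvements act on the four primary
adoption inflows and every drag; education and culture levers act on
their name-matched flows.

## Calibration

Each packaged scenario ships a frozen parameter file fitted to that
scenario's reported trajectory features — peak level, peak window,
terminal level, or values at specific years. The fit is nested and
deterministic:

1. the adoption scale α acts monotonically on the stock's level, so
   for any trial attrition pair it is solved *exactly* by bracketed
   bisection against the primary feature (the peak, or the first
   year-value);
2. a bounded Nelder–Mead over log(δ₀, γ) matches the remaining
   features (peak-window violations enter as a hinge in years; value
   residuals are scaled relative). The log parameterization keeps
   rates positive; the nesting avoids the degenerate ridge δ₀ → 0,
   γ → ∞ that a joint simplex falls into.

Outcome stocks are fitted sequentially in causal order (engagement,
then satisfaction and communication, then outcomes), and intervention
scenarios are fitted with their documented level active, starting from
the baseline fit. Scenarios are calibrated **independently** because
the reported magnitudes are mutually inconsistent under any single
parameterization (a baseline outcomes peak near 6.8 M versus a
10%-intervention run near 1.25 M in 2025); the package reproduces each
reported run as its own frozen scenario rather than silently
reconciling them.

One structural limit is worth knowing: with attrition linear in time,
δ(2032)/δ(t_peak) ≤ 10/(t_peak − 2022), which bounds how far a stock
can fall by 2032 once its peak lies inside the reported window. A
terminal level of essentially zero is therefore not reachable jointly
with a 2022–2023 peak; the frozen calibrations use attainable terminal
levels (engagement 0.15 M, satisfaction 0.4 M, communication 0.4 M,
outcomes 1.5 M) while matching the reported peaks and year-values
exactly. Carrying capacities K are fixed per scenario (3–14 M) rather
than fitted; they set the headroom the saturation term needs above each
target peak.

## Feedback-loop analysis

The causal loop diagram is a signed digraph; loop polarity follows the
parity rule (REINFORCING iff the number of negative links is even,
equivalent to a positive product of link signs). Enumeration uses
simple-cycle search bounded by a maximum length (default 12) and a
cycle cap (default 10 000) to guard dense graphs; cycles are
canonicalized to start at their lexicographically smallest node, which
makes output independent of input edge order. The packaged diagram
encodes six reinforcing loops (the patient-centric care chain, the
intention/usefulness chain, two technology-integration loops, a
digital-health loop, a resource-optimization loop) and one balancing
loop — the insurance authorization process, whose review-denial link is
the diagram's only negative edge. The exact published edge list is not
available as data, so every packaged edge carries a provenance note
naming the narrative relationship it encodes; the loop memberships of
the individually numbered reinforcing loops are inferred, not asserted
as ground truth.

## Trajectory summaries

Peaks report the maximum saved value and the earliest time achieving it
(ties break early). `value_at` interpolates linearly between saved
samples. Histograms bin the trajectory's values over its saved time
samples into half-open bins [k·w, (k+1)·w) anchored at 0 with default
width 0.1 M — the reading of a per-run value-frequency plot. Skewness
is the standard adjusted Fisher–Pearson statistic (the bias factor
applied to m₃/s³ with the (n−1)-denominator s). Note a terminology
trap: a trajectory that lingers near zero has most histogram mass in
the lowest bin, which is a *positively* (right-) skewed distribution in
the moment convention, even though such plots are sometimes informally
described as left-skewed; the package implements the standard statistic
and takes no side on the informal usage.

## Sensitivity analysis

Sweeps integrate the scenario once per level on a shared grid.
Divergence between two levels is the maximum absolute gap of the
outcome series over time (with the earliest achieving time); it is
symmetric and zero on identical levels. An L2-over-time variant exists
but the max-gap is the headline metric, chosen for interpretability.
One-at-a-time elasticities are central differences of the outcome peak
on log scales, (Δpeak/peak)/(Δparam/param), with a 5% default relative
step — a documented convention, verified in the tests against the
closed-form elasticity r·T of exponential growth.

## Synthetic data and recovery

The study design rests entirely on simulated trajectories, so the
package carries its own synthetic-data stage. Parameter ensembles are
drawn from declared ranges, either independently uniform or by Latin
hypercube (exactly one draw per stratum per parameter); observation
noise is additive zero-mean Gaussian per saved sample, clamped at zero
for population series — the simplest observation model, stated rather
than inherited, since no generating mechanism was published. Parameter
recovery minimizes the sum of squared deviations between the observed
series and the re-simulated model over the chosen free parameters,
using bounded Nelder–Mead from the scenario defaults (iteration cap
500, objective tolerance 1e-8) — the objective is cheap (one 1280-step
integration, ≈30 ms) and low-dimensional, so a derivative-free local
search suffices. Every stochastic operation is a pure function of its
inputs and an integer seed.

What the synthetic stage emulates — and what it does not: it reproduces
the *structure* of simulation-only studies (known generating model,
controllable noise, seeded replication) and therefore supports
estimator validation; it does not emulate real-world measurement
(reporting delays, censoring, demographic heterogeneity, behavioral
feedback on observation), so passing recovery tests says the pipeline
is self-consistent, not that the model is identified from real data.

## Problem sizes used in the tests

The default suite integrates the full model at the production step
(1280 Euler steps per run) for scenario checks; sweeps and recovery use
the 16-step save stride (81 saved samples). The loop-analysis oracle
compares against exhaustive cycle enumeration on random digraphs of up
to 8 nodes over 200 seeds; recovery robustness uses 20 noise seeds with
σ = 0.05 M on the engagement series. These sizes make the whole suite
run in well under a minute while exercising every code path at the
production resolution.

## Known limitations

- The reconstructed equations are *a* family consistent with the
  reported features, not the original model; quantities away from the
  calibrated features (e.g. mid-horizon values of uncalibrated stocks)
  carry no fidelity claim.
- Per-scenario calibration means cross-scenario comparisons other than
  the packaged sweeps are not meaningful.
- Supporting stocks are deliberately simple (Data Privacy and Patient
  Health Status, for instance, accumulate monotonically).
- No unit checking beyond metadata; no higher-order or adaptive
  integrators (forward Euler at a 3-day step is the study design, and
  the convergence tests characterize its first-order error).
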