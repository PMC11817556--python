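"""Synthetic data: seeded ensembles (LHS stratification), observation
noise, constant-net-flow fitting, and parameter recovery."""

import numpy as np
import pytest

from patientflow import (
    EnsembleSpec,
    ParameterSet,
    Sampling,
    ScenarioConfig,
    Trajectory,
    add_observation_noise,
    build_reference_model,
    fit_constant_net_flow,
    integrate,
    recover_parameters,
    sample_ensemble,
)
from patientflow.engine import SimSettings
from patientflow.synth import SynthError


class TestSampleEnsemble:
    def test_degenerate_range_pins_the_value(self):
        spec = EnsembleSpec(ranges={"a": (2.0, 2.0 + 1e-9)}, n=1, seed=0)
        (ps,) = sample_ensemble(spec)
        assert abs(ps["a"] - 2.0) <= 1e-9

    def test_same_seed_reproduces_different_seed_does_not(self):
        spec = EnsembleSpec(ranges={"a": (0.0, 1.0), "b": (5.0, 9.0)}, n=8, seed=11)
        again = EnsembleSpec(ranges={"a": (0.0, 1.0), "b": (5.0, 9.0)}, n=8, seed=11)
        other = EnsembleSpec(ranges={"a": (0.0, 1.0), "b": (5.0, 9.0)}, n=8, seed=12)
        assert sample_ensemble(spec) == sample_ensemble(again)
        assert sample_ensemble(spec) != sample_ensemble(other)

    @pytest.mark.parametrize("sampling", list(Sampling))
    def test_samples_respect_ranges(self, sampling):
        spec = EnsembleSpec(
            ranges={"a": (-3.0, -1.0), "b": (10.0, 20.0)}, n=50, seed=4,
            sampling=sampling)
        for ps in sample_ensemble(spec):
            assert -3.0 <= ps["a"] <= -1.0
            assert 10.0 <= ps["b"] <= 20.0

    def test_latin_hypercube_hits_every_decile_exactly_once(self):
        spec = EnsembleSpec(
            ranges={"p": (0.0, 1.0)}, n=10, seed=3,
            sampling=Sampling.LATIN_HYPERCUBE)
        values = sorted(ps["p"] for ps in sample_ensemble(spec))
        strata = [int(v * 10) for v in values]
        assert strata == list(range(10))

    def test_lhs_stratifies_every_parameter(self):
        spec = EnsembleSpec(
            ranges={"a": (0.0, 2.0), "b": (-1.0, 0.0)}, n=5, seed=9,
            sampling=Sampling.LATIN_HYPERCUBE)
        draws = sample_ensemble(spec)
        for name, (lo, hi) in spec.ranges.items():
            strata = sorted(
                int((ps[name] - lo) / (hi - lo) * 5) for ps in draws)
            assert strata == list(range(5))

    def test_empty_and_inverted_ranges_rejected(self):
        with pytest.raises(SynthError) as err:
            EnsembleSpec(ranges={}, n=1, seed=0)
        assert err.value.code == "EMPTY_RANGES"
        with pytest.raises(SynthError):
            EnsembleSpec(ranges={"a": (1.0, 1.0)}, n=1, seed=0)


class TestObservationNoise:
    def _flat(self, n=10_000):
        times = 2022.0 + 0.001 * np.arange(n)
        return Trajectory(times=times, series={"x": np.zeros(n)})

    def test_sigma_zero_is_identity(self, coarse_baseline_traj):
        ns = add_observation_noise(coarse_baseline_traj, "Patient Engagement",
                                   0.0, seed=5)
        assert np.array_equal(ns.values, coarse_baseline_traj["Patient Engagement"])

    def test_noise_mean_within_clt_bound(self):
        ns = add_observation_noise(self._flat(), "x", 1.0, seed=17, clamp=False)
        assert abs(np.mean(ns.values)) <= 3.0 / np.sqrt(10_000)

    def test_same_seed_identical_perturbations(self, coarse_baseline_traj):
        a = add_observation_noise(coarse_baseline_traj, "Patient Engagement", 0.1, seed=2)
        b = add_observation_noise(coarse_baseline_traj, "Patient Engagement", 0.1, seed=2)
        assert np.array_equal(a.values, b.values)

    def test_clamping_keeps_series_non_negative(self):
        ns = add_observation_noise(self._flat(100), "x", 1.0, seed=0)
        assert np.all(ns.values >= 0.0)

    def test_unknown_variable(self, coarse_baseline_traj):
        with pytest.raises(SynthError) as err:
            add_observation_noise(coarse_baseline_traj, "nope", 0.1, seed=0)
        assert err.value.code == "UNKNOWN_VARIABLE"


class TestFitConstantNetFlow:
    def test_worked_example_slope_is_fifty(self):
        times = np.linspace(2022.0, 2025.0, 25)
        values = 1000.0 + 50.0 * (times - 2022.0)
        assert fit_constant_net_flow(times, values) == pytest.approx(50.0)

    def test_constant_series_slope_zero(self):
        assert fit_constant_net_flow([2022.0, 2023.0, 2024.0], [7, 7, 7]) == 0.0

    def test_noisy_linear_series_within_three_standard_errors(self):
        rng = np.random.default_rng(123)
        times = np.linspace(2022.0, 2032.0, 1281)
        values = 1000.0 + 50.0 * (times - 2022.0) + rng.normal(0, 5.0, 1281)
        # OLS slope standard error: sigma / sqrt(sum (t - tbar)^2)
        se = 5.0 / np.sqrt(np.sum((times - times.mean()) ** 2))
        assert abs(fit_constant_net_flow(times, values) - 50.0) <= 3 * se

    def test_degenerate_times_rejected(self):
        with pytest.raises(SynthError) as err:
            fit_constant_net_flow([2022.0, 2022.0], [1.0, 2.0])
        assert err.value.code == "DEGENERATE_TIMES"
        with pytest.raises(SynthError):
            fit_constant_net_flow([2022.0], [1.0])


class TestRecoverParameters:
    def test_empty_free_list_returns_defaults_and_residual(
            self, baseline_scenario, coarse_baseline_traj):
        noisy = add_observation_noise(
            coarse_baseline_traj, "Patient Engagement", 0.05, seed=1)
        result = recover_parameters(noisy, baseline_scenario, [])
        assert result.parameters == baseline_scenario.parameters
        assert result.sse > 0
        assert result.converged

    def test_noise_free_recovery_of_perturbed_truth_within_one_percent(
            self, baseline_scenario):
        true_alpha = baseline_scenario.parameters["alpha_pe"] * 1.2
        truth = ScenarioConfig(
            "baseline", baseline_scenario.parameters.updated(alpha_pe=true_alpha))
        observed_traj = integrate(
            build_reference_model(truth), SimSettings(save_every=16))
        observed = add_observation_noise(
            observed_traj, "Patient Engagement", 0.0, seed=0)
        result = recover_parameters(observed, baseline_scenario, ["alpha_pe"])
        assert result.parameters["alpha_pe"] == pytest.approx(true_alpha, rel=0.01)

    def test_noisy_recovery_within_five_percent(self, baseline_scenario):
        true_alpha = baseline_scenario.parameters["alpha_pe"] * 1.15
        truth = ScenarioConfig(
            "baseline", baseline_scenario.parameters.updated(alpha_pe=true_alpha))
        observed_traj = integrate(
            build_reference_model(truth), SimSettings(save_every=16))
        observed = add_observation_noise(
            observed_traj, "Patient Engagement", 0.05, seed=7)
        result = recover_parameters(observed, baseline_scenario, ["alpha_pe"])
        assert result.parameters["alpha_pe"] == pytest.approx(true_alpha, rel=0.05)

    def test_unknown_free_parameter_rejected(self, baseline_scenario,
                                             coarse_baseline_traj):
        noisy = add_observation_noise(
            coarse_baseline_traj, "Patient Engagement", 0.0, seed=0)
        with pytest.raises(SynthError) as err:
            recover_parameters(noisy, baseline_scenario, ["no_such"])
        assert err.value.code == "UNKNOWN_PARAMETER"

    def test_recovery_error_shrinks_with_noise(self, baseline_scenario):
        """Averaged over a few seeds, smaller observation noise gives a
        recovery at least as accurate (weak monotonicity over the sigma
        grid)."""
        true_alpha = baseline_scenario.parameters["alpha_pe"] * 1.2
        truth = ScenarioConfig(
            "baseline", baseline_scenario.parameters.updated(alpha_pe=true_alpha))
        observed_traj = integrate(
            build_reference_model(truth), SimSettings(save_every=16))

        def mean_err(sigma):
            errs = []
            for seed in range(3):
                observed = add_observation_noise(
                    observed_traj, "Patient Engagement", sigma, seed=seed)
                result = recover_parameters(observed, baseline_scenario, ["alpha_pe"])
                errs.append(abs(result.parameters["alpha_pe"] / true_alpha - 1.0))
            return float(np.mean(errs))

        assert mean_err(0.0) <= mean_err(0.2) + 1e-9
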