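"""Engine: validation ordering, the Euler update, exactness for constant
rates, first-order convergence, conservation and determinism."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from patientflow import (
    BOUNDARY,
    AuxiliaryDef,
    EngineError,
    FlowDef,
    ModelSpec,
    ModelValidationError,
    ParameterSet,
    SimSettings,
    StockDef,
    closed_form_constant_flows,
    euler_step,
    integrate,
    validate_model,
)


def one_stock_model(rate_in: str, rate_out: str = "0", s0: float = 0.0,
                    non_negative: bool = True, params: dict | None = None,
                    auxiliaries=()) -> ModelSpec:
    return ModelSpec(
        stocks=(StockDef("S", s0, non_negative=non_negative),),
        flows=(
            FlowDef("in", BOUNDARY, "S", rate_in),
            FlowDef("out", "S", BOUNDARY, rate_out),
        ),
        auxiliaries=tuple(auxiliaries),
        parameters=ParameterSet(params or {}),
    )


class TestValidateModel:
    def test_no_auxiliaries_gives_empty_plan(self, const_flow_spec):
        plan = validate_model(const_flow_spec)
        assert plan.aux_order == ()

    def test_chain_ordering_against_permutation_oracle(self, chain_aux_spec):
        """The returned order must be one of the orders the dependency
        relation admits — checked by brute force over all permutations."""
        plan = validate_model(chain_aux_spec)
        deps = {"a": set(), "b": {"a"}, "c": {"b"}}
        valid = {
            perm
            for perm in itertools.permutations("abc")
            if all(dep in perm[:i] for i, name in enumerate(perm) for dep in deps[name])
        }
        assert plan.aux_order in valid
        assert plan.aux_order == ("a", "b", "c")  # only one order is admissible

    def test_mutual_dependency_reports_algebraic_loop(self):
        spec = ModelSpec(
            stocks=(StockDef("S", 0.0),),
            flows=(),
            auxiliaries=(AuxiliaryDef("x", "y + 1"), AuxiliaryDef("y", "x + 1")),
            parameters=ParameterSet({}),
        )
        with pytest.raises(ModelValidationError) as err:
            validate_model(spec)
        loops = [i for i in err.value.issues if i.code == "ALGEBRAIC_LOOP"]
        assert loops and set(loops[0].symbols) == {"x", "y"}

    def test_all_violations_reported_together(self):
        spec = ModelSpec(
            stocks=(StockDef("S", 0.0), StockDef("S", 1.0)),
            flows=(FlowDef("f", "S", "Ghost", "missing_param"),),
            auxiliaries=(),
            parameters=ParameterSet({}),
        )
        with pytest.raises(ModelValidationError) as err:
            validate_model(spec)
        codes = {i.code for i in err.value.issues}
        assert {"DUPLICATE_NAME", "UNKNOWN_SYMBOL"} <= codes
        assert len(err.value.issues) >= 3  # duplicate, bad endpoint, bad symbol


class TestEulerStep:
    def test_worked_engagement_example(self, const_flow_spec):
        new = euler_step({"Patient Engagement": 1000.0}, const_flow_spec, 2022.0, 1.0)
        assert new["Patient Engagement"] == 1050.0

    def test_half_step(self, const_flow_spec):
        new = euler_step({"Patient Engagement": 1000.0}, const_flow_spec, 2022.0, 0.5)
        assert new["Patient Engagement"] == 1025.0

    def test_zero_rates_leave_state_unchanged(self):
        spec = one_stock_model("0", "0", s0=7.0)
        assert euler_step({"S": 7.0}, spec, 2022.0, 0.25) == {"S": 7.0}

    def test_non_negative_stock_clamps_at_zero(self):
        spec = one_stock_model("0", "10", s0=1.0)
        assert euler_step({"S": 1.0}, spec, 2022.0, 1.0) == {"S": 0.0}

    def test_state_dict_is_not_mutated(self, const_flow_spec):
        state = {"Patient Engagement": 1000.0}
        euler_step(state, const_flow_spec, 2022.0, 1.0)
        assert state == {"Patient Engagement": 1000.0}


class TestIntegrate:
    @pytest.mark.parametrize("dt", [1.0, 0.0078125])
    def test_constant_flows_exact_at_2025(self, const_flow_spec, dt):
        """Euler is exact for constant rates: 1000 + 3yr * 50/yr = 1150,
        independent of the step size."""
        traj = integrate(const_flow_spec, SimSettings(dt=dt))
        idx = int(np.where(traj.times == 2025.0)[0][0])
        assert traj["Patient Engagement"][idx] == 1150.0

    def test_all_flows_zero_keeps_stocks_constant(self):
        spec = one_stock_model("0", "0", s0=3.25)
        traj = integrate(spec, SimSettings(dt=0.125))
        assert np.all(traj["S"] == 3.25)

    def test_matches_closed_form_at_every_saved_time(self, const_flow_spec):
        traj = integrate(const_flow_spec, SimSettings(dt=0.0625, save_every=4))
        expected = [
            closed_form_constant_flows(1000.0, 100.0, 50.0, 2022.0, t)
            for t in traj.times
        ]
        np.testing.assert_allclose(traj["Patient Engagement"], expected, rtol=1e-13)

    def test_series_contains_stocks_flows_and_auxiliaries(self):
        spec = one_stock_model(
            "a", "0", params={"k": 2.0}, auxiliaries=(AuxiliaryDef("a", "k"),))
        traj = integrate(spec, SimSettings(tf=2023.0, dt=0.5))
        assert set(traj.series) == {"S", "in", "out", "a"}
        assert np.all(traj["a"] == 2.0)

    def test_save_every_thins_the_grid_but_keeps_endpoints(self, const_flow_spec):
        traj = integrate(const_flow_spec, SimSettings(dt=0.0078125, save_every=16))
        assert traj.times[0] == 2022.0 and traj.times[-1] == 2032.0
        assert len(traj.times) == 81

    def test_first_order_convergence_against_fine_oracle(self):
        """Nonlinear rate: halving dt must roughly halve the max error
        against a 100x-finer reference run (ratio in [1.8, 2.2])."""
        def make():
            return one_stock_model(
                "r * [S] * (1 - [S] / 10)", "0", s0=0.5, params={"r": 0.8})

        fine = integrate(make(), SimSettings(tf=2027.0, dt=0.0025, save_every=100))
        coarse = integrate(make(), SimSettings(tf=2027.0, dt=0.25, save_every=1))
        half = integrate(make(), SimSettings(tf=2027.0, dt=0.125, save_every=2))
        ref = fine["S"]
        err_coarse = np.max(np.abs(coarse["S"] - ref))
        err_half = np.max(np.abs(half["S"] - ref))
        assert 1.8 <= err_coarse / err_half <= 2.2

    def test_closed_two_stock_conservation(self):
        spec = ModelSpec(
            stocks=(StockDef("A", 10.0), StockDef("B", 2.0)),
            flows=(FlowDef("transfer", "A", "B", "0.7 * [A]"),),
            auxiliaries=(),
            parameters=ParameterSet({}),
        )
        traj = integrate(spec, SimSettings())
        total = traj["A"] + traj["B"]
        assert np.max(np.abs(total - 12.0)) / 12.0 <= 1e-9

    def test_bit_identical_reruns(self, const_flow_spec):
        a = integrate(const_flow_spec, SimSettings())
        b = integrate(const_flow_spec, SimSettings())
        assert a == b

    def test_nonfinite_rate_reports_flow_step_and_time(self):
        spec = one_stock_model("1 / (time - 2023)", "0")
        with pytest.raises(EngineError) as err:
            integrate(spec, SimSettings(tf=2024.0, dt=0.5))
        assert err.value.code == "NONFINITE_RATE"
        assert err.value.time == 2023.0
        assert err.value.step == 2

    def test_negative_rates_are_floored_at_zero(self):
        traj = integrate(one_stock_model("-5", "0", s0=1.0),
                         SimSettings(tf=2023.0, dt=0.5))
        assert np.all(traj["S"] == 1.0)
        assert np.all(traj["in"] == 0.0)


class TestClosedForm:
    def test_worked_example(self):
        assert closed_form_constant_flows(1000.0, 100.0, 50.0, 2022.0, 2025.0) == 1150.0

    def test_zero_length_interval(self):
        assert closed_form_constant_flows(5.0, 3.0, 1.0, 2022.0, 2022.0) == 5.0

    @pytest.mark.parametrize("c", [0.0, 1.0, 123.4])
    def test_balanced_flows(self, c):
        assert closed_form_constant_flows(5.0, c, c, 2022.0, 2030.0) == 5.0

    def test_rejects_reversed_interval(self):
        with pytest.raises(ValueError):
            closed_form_constant_flows(1.0, 1.0, 1.0, 2025.0, 2022.0)


class TestSettings:
    def test_rejects_non_integer_step_count(self):
        with pytest.raises(ValueError):
            SimSettings(t0=2022.0, tf=2032.0, dt=0.3)

    @pytest.mark.parametrize("kw", [
        {"tf": 2020.0}, {"dt": -0.1}, {"save_every": 0}, {"method": "RK4"},
    ])
    def test_rejects_bad_settings(self, kw):
        with pytest.raises(ValueError):
            SimSettings(**kw)

    def test_table_settings_give_1280_steps(self):
        assert SimSettings().n_steps == 1280


@given(
    s0=st.floats(0.0, 1e4),
    inflow=st.floats(0.0, 1e3),
    outflow=st.floats(0.0, 1e3),
)
def test_euler_equals_closed_form_for_any_constant_rates(s0, inflow, outflow):
    """Property: with constant rates the discrete sum telescopes to the
    closed form at the final time (clamping disabled)."""
    spec = ModelSpec(
        stocks=(StockDef("S", s0, non_negative=False),),
        flows=(
            FlowDef("in", BOUNDARY, "S", repr(inflow)),
            FlowDef("out", "S", BOUNDARY, repr(outflow)),
        ),
        auxiliaries=(),
        parameters=ParameterSet({}),
    )
    traj = integrate(spec, SimSettings(tf=2026.0, dt=0.25, save_every=16))
    expected = closed_form_constant_flows(s0, inflow, outflow, 2022.0, 2026.0)
    assert traj["S"][-1] == pytest.approx(expected, rel=1e-12, abs=1e-9)
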