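"""Unit tests for model types, validation, and term/RHS evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbst.model import (ModelSpec, ModelValidationError, PowerDomainError,
                        PowerLawTerm, Regime, RegimeSet, VariableSpec,
                        evaluate_term, rhs, validate_model)
from dbst.models import linear_pathway


def two_var_spec(**kwargs):
    return ModelSpec(
        name="toy",
        variables=[VariableSpec("X1", "dependent", 1.0),
                   VariableSpec("X2", "dependent", 1.3)],
        equations={
            "X1": [PowerLawTerm(0.011, {"X1": 2.0, "X2": 3.0}, sign=+1),
                   PowerLawTerm(0.011, {"X1": 1.0, "X2": 1.0}, sign=-1)],
            "X2": [PowerLawTerm(1.0, {"X1": 1.0}, sign=+1),
                   PowerLawTerm(1.0, {"X2": 1.0}, sign=-1)],
        },
        step_size=0.1,
        **kwargs,
    )


class TestValidation:
    def test_linear_pathway_fixture_is_valid(self):
        spec = linear_pathway()  # builder validates internally
        assert len(spec.dependent_names) == 2
        assert sum(len(spec.terms_of(v)) for v in spec.dependent_names) == 4

    def test_unknown_exponent_variable_is_named(self):
        spec = two_var_spec()
        spec.equations["X1"].append(PowerLawTerm(1.0, {"X9": 1.0}, sign=+1))
        with pytest.raises(ModelValidationError, match="X9"):
            validate_model(spec)

    def test_delay_snaps_to_grid_with_warning(self):
        spec = two_var_spec()
        spec.equations["X1"][0].delay = {"X2": 3.05}
        with pytest.warns(UserWarning, match="snapped"):
            out = validate_model(spec)
        snapped = out.equations["X1"][0].delay["X2"]
        assert snapped == pytest.approx(round(3.05 / 0.1) * 0.1, abs=1e-12)
        assert round(snapped / 0.1) * 0.1 == snapped  # lies on the grid

    def test_strict_mode_rejects_off_grid_delay(self):
        spec = two_var_spec()
        spec.equations["X1"][0].delay = {"X2": 3.04}
        with pytest.raises(ModelValidationError, match="delay"):
            validate_model(spec, strict=True)

    def test_negative_rate_constant_normalized_to_signed_form(self):
        spec = two_var_spec()
        spec.equations["X2"] = [PowerLawTerm(-2.0, {"X1": 1.0}, sign=+1),
                                PowerLawTerm(1.0, {"X2": 1.0}, sign=-1)]
        out = validate_model(spec)
        term = out.equations["X2"][0]
        assert term.rate_constant == 2.0 and term.sign == -1

    def test_empty_equation_list_rejected(self):
        spec = two_var_spec()
        spec.equations["X2"] = []
        with pytest.raises(ModelValidationError, match="empty"):
            validate_model(spec)

    def test_collects_multiple_violations(self):
        spec = two_var_spec()
        spec.equations["X1"][0].exponents["X9"] = 1.0
        spec.equations["X2"] = []
        spec.variables.append(VariableSpec("X1", "dependent", math.nan))
        with pytest.raises(ModelValidationError) as exc:
            validate_model(spec)
        assert len(exc.value.violations) >= 3

    def test_event_process_must_target_independent_variable(self):
        from dbst.stochastic import EventProcess
        spec = two_var_spec(event_processes=[
            EventProcess("X1", "table", table=[(0.0, 1.0)])])
        with pytest.raises(ModelValidationError, match="dependent"):
            validate_model(spec)


class TestEvaluateTerm:
    def test_hand_computed_power_product(self):
        # 0.011 · 1² · 1.3³, cross-checked in log space
        term = PowerLawTerm(0.011, {"X1": 2.0, "X2": 3.0})
        got = evaluate_term(term, {"X1": 1.0, "X2": 1.3})
        log_space = math.exp(math.log(0.011) + 2 * math.log(1.0) + 3 * math.log(1.3))
        assert got == pytest.approx(0.024167, abs=1e-6)
        assert got == pytest.approx(log_space, rel=1e-12)

    def test_efflux_at_steady_state_balances_influx(self):
        # 2.5 · 0.64^0.5 = 2.0, the constant influx 2·X0 of the linear pathway
        term = PowerLawTerm(2.5, {"X2": 0.5})
        assert evaluate_term(term, {"X2": 0.64}) == pytest.approx(2.0, abs=1e-12)

    def test_empty_product_returns_rate_constant(self):
        term = PowerLawTerm(1.75, {"X1": 0.0})
        assert evaluate_term(term, {"X1": 123.0}) == 1.75

    def test_fractional_power_of_nonpositive_base_raises(self):
        term = PowerLawTerm(1.0, {"X1": 0.5})
        with pytest.raises(PowerDomainError, match="X1"):
            evaluate_term(term, {"X1": -0.1})

    def test_clamp_mode_uses_floor_instead_of_raising(self):
        term = PowerLawTerm(1.0, {"X1": 0.5})
        got = evaluate_term(term, {"X1": -0.1}, clamp=True, clamp_floor=1e-12)
        assert got == pytest.approx(math.sqrt(1e-12))

    def test_offset_keeps_inhibition_finite_at_zero(self):
        # the (X+1)^g device: at X=0 the factor is exactly 1
        term = PowerLawTerm(3.0, {"X6": -4.0}, offset={"X6": 1.0})
        assert evaluate_term(term, {"X6": 0.0}) == pytest.approx(3.0)
        assert evaluate_term(term, {"X6": 1.0}) == pytest.approx(3.0 / 16.0)

    def test_noise_draw_multiplies_flux(self):
        term = PowerLawTerm(2.0, {"X1": 1.0}, noise_id="s")
        assert evaluate_term(term, {"X1": 1.5}, noise_draws={"s": 0.9}) == \
            pytest.approx(2.7)

    @settings(deadline=None, derandomize=True)
    @given(gamma=st.floats(0.01, 100), scale=st.floats(0.1, 10),
           x=st.floats(0.1, 5), f=st.floats(-3, 3))
    def test_positively_homogeneous_in_rate_constant(self, gamma, scale, x, f):
        t1 = PowerLawTerm(gamma, {"X": f})
        t2 = PowerLawTerm(gamma * scale, {"X": f})
        v1 = evaluate_term(t1, {"X": x})
        assert evaluate_term(t2, {"X": x}) == pytest.approx(scale * v1, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(gamma=st.floats(0.01, 10),
           exps=st.lists(st.integers(0, 4), min_size=1, max_size=3),
           vals=st.lists(st.floats(0.1, 3), min_size=3, max_size=3))
    def test_integer_exponents_match_repeated_multiplication(self, gamma, exps, vals):
        names = [f"X{i}" for i in range(len(exps))]
        term = PowerLawTerm(gamma, dict(zip(names, map(float, exps))))
        state = dict(zip(names, vals))
        expected = gamma
        for n, e in zip(names, exps):
            for _ in range(e):
                expected *= state[n]
        assert evaluate_term(term, state) == pytest.approx(expected, rel=1e-12)


class TestRhs:
    def test_zero_at_analytic_fixed_point(self):
        spec = linear_pathway()
        x1 = (2.0 / 1.75) ** (1 / 0.8)
        f = rhs(spec, {"X0": 1.0, "X1": x1, "X2": 0.64})
        assert np.max(np.abs(f)) < 1e-10

    def test_hand_computed_net_change_near_fixed_point(self):
        spec = linear_pathway()
        f = rhs(spec, {"X0": 1.0, "X1": 1.18, "X2": 0.64})
        expected_f1 = 2.0 - 1.75 * math.exp(0.8 * math.log(1.18))
        assert f[0] == pytest.approx(expected_f1, rel=1e-12)
        assert expected_f1 == pytest.approx(0.002239, abs=1e-6)
        assert f[1] == pytest.approx(-expected_f1, rel=1e-12)

    def test_threshold_regimes_switch_term_lists(self):
        low_terms = Regime([PowerLawTerm(0.018, {}, sign=+1),
                            PowerLawTerm(0.1, {"X1": 1.0}, sign=-1)])
        mid_terms = Regime([PowerLawTerm(0.2, {"X3": 2.0}, sign=+1),
                            PowerLawTerm(0.1, {"X1": 1.0}, sign=-1)])
        high_terms = Regime([PowerLawTerm(0.098, {}, sign=+1),
                             PowerLawTerm(0.1, {"X1": 1.0}, sign=-1)])
        spec = ModelSpec(
            name="switch",
            variables=[VariableSpec("X1", "dependent", 0.0),
                       VariableSpec("X3", "independent", 0.5)],
            equations={"X1": RegimeSet("X3", 0.3, 0.7, low_terms, mid_terms,
                                       high_terms)},
            step_size=0.1)
        spec = validate_model(spec)

        def f1(x3):
            return rhs(spec, {"X1": 0.0, "X3": x3})[0]

        assert f1(0.1) == pytest.approx(0.018)        # below threshold
        assert f1(0.5) == pytest.approx(0.2 * 0.25)   # responsive regime
        assert f1(0.9) == pytest.approx(0.098)        # saturated
        # boundaries belong to the middle regime (inclusive on both ends)
        assert f1(0.3) == pytest.approx(0.2 * 0.09)
        assert f1(0.7) == pytest.approx(0.2 * 0.49)
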