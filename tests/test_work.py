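"""Work-of-breathing closed forms against the numeric-integration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wobkit import (
    FlowComponent,
    FlowSignal,
    RespiratoryMechanics,
    VentilationSpec,
    WorkBreakdown,
    compose_inspiration,
    halfsine_impulse,
    amplitude_for_tidal,
    is_limit,
    mean_work_nonsinusoidal,
    mean_work_sinusoidal,
    tidal_from_ventilation,
    total_force,
    work_numeric,
    work_single_breath,
)

MECH = RespiratoryMechanics()  # K=8.52, K'=3.5, K''=1.5


def halfsine_signal(v_t: float, f: float, dt: float) -> FlowSignal:
    """Half-sine inspiratory lobe delivering v_t litres at frequency f."""
    return halfsine_impulse(FlowComponent(amplitude_for_tidal(v_t, f), f), dt)


class TestTotalForce:
    def test_zero_state_zero_force(self):
        assert total_force(0.0, 0.0, MECH) == 0.0

    def test_elastic_term_alone(self):
        assert total_force(1.0, 0.0, MECH) == pytest.approx(8.52)

    def test_all_terms(self):
        # 8.52*0.5 + 3.5*1 + 1.5*1 = 9.26
        assert total_force(0.5, 1.0, MECH) == pytest.approx(9.26)

    @given(v=st.floats(-2, 2), dvdt=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_quadratic_in_flow(self, v, dvdt):
        expected = MECH.K * v + MECH.K_prime * dvdt + MECH.K_doubleprime * dvdt**2
        assert total_force(v, dvdt, MECH) == pytest.approx(expected)


class TestWorkSingleBreath:
    def test_reference_breath_components(self):
        wb = work_single_breath(1.0, 0.25, MECH)
        assert wb.elastic == pytest.approx(4.26)
        assert wb.viscous == pytest.approx(2.1590, abs=5e-5)
        assert wb.turbulent == pytest.approx(0.6169, abs=5e-5)
        assert wb.total == pytest.approx(7.0359, abs=2e-4)

    def test_elastic_only_limit_is_frequency_free(self):
        mech = RespiratoryMechanics(K=8.52, K_prime=0.0, K_doubleprime=0.0)
        w1 = work_single_breath(0.8, 0.25, mech)
        w2 = work_single_breath(0.8, 1.5, mech)
        assert w1.total == w2.total == pytest.approx(0.5 * 8.52 * 0.64)

    def test_frequency_scaling_of_components(self):
        w1 = work_single_breath(0.7, 0.3, MECH)
        w2 = work_single_breath(0.7, 0.6, MECH)
        assert w2.viscous == pytest.approx(2 * w1.viscous)
        assert w2.turbulent == pytest.approx(4 * w1.turbulent)
        assert w2.elastic == w1.elastic

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            work_single_breath(0.0, 1.0, MECH)
        with pytest.raises(ValueError):
            work_single_breath(1.0, -0.5, MECH)

    @given(v_t=st.floats(0.2, 2.0), f=st.floats(0.1, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_additivity(self, v_t, f):
        wb = work_single_breath(v_t, f, MECH)
        assert wb.total == wb.elastic + wb.viscous + wb.turbulent


class TestWorkNumericOracle:
    def test_halfsine_matches_closed_form(self):
        sig = halfsine_signal(1.0, 0.25, dt=1e-4)
        num = work_numeric(sig, MECH)
        ref = work_single_breath(1.0, 0.25, MECH)
        for name in ("elastic", "viscous", "turbulent", "total"):
            rel = abs(getattr(num, name) - getattr(ref, name)) / getattr(ref, name)
            assert rel < 1e-4, name

    def test_refining_dt_reduces_error_order_at_least_one(self):
        ref = work_single_breath(1.0, 0.25, MECH).total
        errors = []
        for dt in (4e-4, 2e-4, 1e-4):
            errors.append(abs(work_numeric(halfsine_signal(1.0, 0.25, dt), MECH).total - ref))
        assert errors[1] < errors[0] and errors[2] < errors[1]
        # observed convergence order >= 1
        order = math.log(errors[0] / errors[2]) / math.log(4.0)
        assert order >= 1.0

    def test_zero_signal_zero_work(self):
        wb = work_numeric(FlowSignal(dt=0.01, samples=np.zeros(100)), MECH)
        assert wb.elastic == wb.viscous == wb.turbulent == 0.0

    def test_no_inspiratory_lobe_rejected(self):
        with pytest.raises(ValueError, match="inspiratory"):
            work_numeric(FlowSignal(dt=0.01, samples=-np.ones(50)), MECH)

    def test_multicomponent_breath_exceeds_fundamental_only_estimate(self):
        """A T_I-based characterization sees only the lowest-frequency
        impulse; the composite's true work exceeds what that fundamental
        component alone would predict."""
        dt = 1e-4
        fundamental = FlowComponent(1.0, 0.25)
        comps = [fundamental, FlowComponent(1.0, 1.0)]
        sig = compose_inspiration(comps, dt)
        num = work_numeric(sig, MECH)
        f_from_ti = 1.0 / (2.0 * sig.duration)
        assert f_from_ti == pytest.approx(fundamental.frequency, rel=1e-3)
        fundamental_only = work_single_breath(
            fundamental.tidal_volume, fundamental.frequency, MECH
        )
        assert num.total > fundamental_only.total
        # each resistive component grows as well
        assert num.viscous > fundamental_only.viscous
        assert num.turbulent > fundamental_only.turbulent

    @given(v_t=st.floats(0.3, 1.5), f=st.floats(0.15, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_across_parameters(self, v_t, f):
        dt = 1.0 / (2 * f) / 2000
        num = work_numeric(halfsine_signal(v_t, f, dt), MECH)
        ref = work_single_breath(v_t, f, MECH)
        assert num.total == pytest.approx(ref.total, rel=1e-4)


class TestVentilationSpec:
    @pytest.mark.parametrize("b,v_d,expected", [
        (7.5, 0.2, 1.0), (30.0, 0.2, 0.4), (60.0, 0.0, 0.1),
    ])
    def test_tidal_from_ventilation(self, b, v_d, expected):
        spec = VentilationSpec(V_A=6.0, V_D=v_d, B_rate=b)
        assert tidal_from_ventilation(spec) == pytest.approx(expected)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            VentilationSpec(V_A=6.0, V_D=0.2, B_rate=0.0)


class TestMeanWork:
    def test_slow_rate_total(self):
        spec = VentilationSpec(B_rate=7.5)
        assert mean_work_sinusoidal(spec, MECH).total == pytest.approx(0.6867, abs=5e-5)

    def test_fast_rate_total(self):
        spec = VentilationSpec(B_rate=60.0)
        assert mean_work_sinusoidal(spec, MECH).total == pytest.approx(1.4271, abs=5e-5)

    def test_sinusoidal_equals_numeric_oracle_times_rate(self):
        spec = VentilationSpec(B_rate=7.5)
        per_breath = work_numeric(halfsine_signal(spec.V_T, spec.B_hz, 1e-4), MECH)
        assert mean_work_sinusoidal(spec, MECH).total == pytest.approx(
            per_breath.total * spec.B_hz, rel=1e-4
        )

    def test_elastic_only_sinusoidal(self):
        mech = RespiratoryMechanics(K=8.52, K_prime=0.0, K_doubleprime=0.0)
        spec = VentilationSpec(B_rate=12.0)
        expected = 0.5 * 8.52 * spec.B_hz * spec.V_T**2
        assert mean_work_sinusoidal(spec, mech).total == pytest.approx(expected)

    def test_nonsinusoidal_components_at_slow_rate(self):
        spec = VentilationSpec(B_rate=7.5)
        wb = mean_work_nonsinusoidal(0.25, spec, MECH)
        assert wb.elastic == pytest.approx(0.5325, abs=5e-5)
        assert wb.viscous == pytest.approx(0.269872, abs=5e-5)
        assert wb.turbulent == pytest.approx(0.0771, abs=5e-5)
        assert wb.total == pytest.approx(0.8794, abs=2e-4)

    def test_nonsinusoidal_matches_numeric_oracle(self):
        spec = VentilationSpec(B_rate=7.5)
        per_breath = work_numeric(halfsine_signal(spec.V_T, 0.25, 1e-4), MECH)
        assert mean_work_nonsinusoidal(0.25, spec, MECH).total == pytest.approx(
            per_breath.total * spec.B_hz, rel=1e-4
        )

    def test_infeasible_pairing_is_limit(self):
        assert is_limit(mean_work_nonsinusoidal(0.125, VentilationSpec(B_rate=30.0), MECH))

    @pytest.mark.parametrize("b", [7.5, 15.0, 30.0, 45.0, 60.0])
    def test_diagonal_reduction_to_machine_precision(self, b):
        """At f = B (in Hz) the non-sinusoidal model is the sinusoidal one."""
        spec = VentilationSpec(B_rate=b)
        ns = mean_work_nonsinusoidal(spec.B_hz, spec, MECH)
        s = mean_work_sinusoidal(spec, MECH)
        for name in ("elastic", "viscous", "turbulent"):
            a, bb = getattr(ns, name), getattr(s, name)
            assert abs(a - bb) <= 1e-12 * abs(bb)

    @given(b=st.floats(5.0, 40.0), f=st.floats(0.1, 1.5), scale=st.floats(1.05, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_elastic_invariance_and_monotonicity_in_frequency(self, b, f, scale):
        spec = VentilationSpec(B_rate=b)
        w1 = mean_work_nonsinusoidal(f, spec, MECH)
        w2 = mean_work_nonsinusoidal(f * scale, spec, MECH)
        if is_limit(w1) or is_limit(w2):
            return
        assert w2.elastic == w1.elastic
        assert w2.viscous == pytest.approx(scale * w1.viscous, rel=1e-9)
        assert w2.turbulent == pytest.approx(scale**2 * w1.turbulent, rel=1e-9)
        assert w2.total > w1.total


class TestWorkBreakdownInvariants:
    def test_total_is_exact_sum(self):
        wb = WorkBreakdown(1.0, 0.5, 0.25, basis="per_breath")
        assert wb.total == 1.75

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            WorkBreakdown(-1.0, 0.0, 0.0, basis="per_breath")

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError):
            WorkBreakdown(1.0, 0.0, 0.0, basis="per_minute")
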