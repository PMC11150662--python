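"""Single-element difference-equation system: signals, fixed points, thresholds."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibronet.core_dynamics import (ModelParams, Outcome, classify_outcome,
                                    constant_force_strain, death_probability,
                                    division_probability,
                                    find_critical_weight,
                                    find_fibrotic_threshold, multiplier_grid,
                                    phase_diagram, simulate_element,
                                    steady_state_constant,
                                    stiffness_activation, strain_activation,
                                    total_activation, update_activation,
                                    update_area, update_density)

P = ModelParams()


class TestActivationSignals:
    @pytest.mark.parametrize("A, expected", [
        (10.0, 0.5),                      # half-saturation at the threshold area
        (0.0, 0.0),
        (1.0, 0.001 / 1.001),             # default operating point
    ])
    def test_stiffness_hill(self, A, expected):
        assert stiffness_activation(A, P) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("eps, expected", [
        (1.0, 0.5),
        (0.0, 0.0),
        (3.0, 0.75),
    ])
    def test_strain_hill(self, eps, expected):
        assert strain_activation(eps, P) == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            stiffness_activation(-0.1, P)
        with pytest.raises(ValueError):
            strain_activation(-0.1, P)

    @given(scale=st.floats(0.01, 100.0), beta=st.floats(0.2, 6.0),
           gamma=st.floats(0.2, 6.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_hill_bounds_and_monotonicity(self, scale, beta, gamma):
        p = replace(P, beta=beta, gamma=gamma)
        xs = np.linspace(0.0, 50.0 * scale, 40)
        aK = [stiffness_activation(x, p) for x in xs]
        aE = [strain_activation(x, p) for x in xs]
        for vals in (aK, aE):
            assert all(0.0 <= v <= 1.0 for v in vals)
            # strictly increasing until floating-point saturation
            assert all(b > a or b > 1.0 - 1e-12
                       for a, b in zip(vals, vals[1:]))

    def test_stiffness_saturates(self):
        assert stiffness_activation(1e12, P) == pytest.approx(1.0, abs=1e-6)


class TestSteadyStateConstant:
    def test_default_value(self):
        # w1/2 + w2*(0.1^3)/(0.1^3+1) = 0.5 + 0.001/1.001
        assert steady_state_constant(P) == pytest.approx(0.500999000999, rel=1e-9)
        assert round(P.c, 1) == 0.5

    def test_no_stiffness_term(self):
        p = replace(P, w1=0.8, w2=0.0)
        assert steady_state_constant(p) == pytest.approx(0.4, rel=1e-12)

    def test_double_stiffness_weight(self):
        p = replace(P, w2=2.0)
        assert steady_state_constant(p) == pytest.approx(0.501998001998, rel=1e-9)

    def test_cached_property_coherent(self):
        p = replace(P, w2=2.5, beta=2.0)
        assert p.c == steady_state_constant(p)


class TestTotalActivation:
    def test_exactly_zero_at_homeostasis(self, params):
        a = total_activation(strain_activation(params.eps_s, params),
                             stiffness_activation(params.A0, params), params)
        assert a == 0.0

    def test_bounds(self, params):
        assert total_activation(0.0, 0.0, params) == -params.c
        hi = total_activation(1.0, 1.0, params)
        assert hi == pytest.approx(params.w1 + params.w2 - params.c)

    @given(w1=st.floats(0.1, 3.0), w2=st.floats(0.1, 3.0),
           A0=st.floats(0.1, 2.0), ratio=st.floats(2.0, 50.0),
           eps_s=st.floats(0.2, 3.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_homeostatic_zero_for_any_params(self, w1, w2, A0, ratio, eps_s):
        p = replace(P, w1=w1, w2=w2, A0=A0, At=A0 * ratio, eps_s=eps_s)
        a = total_activation(strain_activation(p.eps_s, p),
                             stiffness_activation(p.A0, p), p)
        assert a == 0.0


class TestStateUpdates:
    def test_activation_memory(self, params):
        # memoryless at the fixed point
        p1 = replace(params, r=1.0)
        assert update_activation(0.7, 0.5, stiffness_activation(1.0, p1), p1) == 0.0
        # frozen activation
        p0 = replace(params, r=0.0)
        assert update_activation(0.3, 0.9, 0.9, p0) == 0.3
        # arithmetic: 0.5*(0.75 + aK(1) - c) = 0.125
        a = update_activation(0.0, 0.75, stiffness_activation(1.0, params), params)
        assert a == pytest.approx(0.125, rel=1e-12)

    def test_area_update(self, params):
        assert update_area(1.0, 0.3, 0.0, params) == 1.0
        assert update_area(1.0, 0.3, 0.5, params) == pytest.approx(1.03)
        # digestion can drive the area non-positive: rupture is signalled,
        # not clamped
        assert update_area(0.01, 1.0, -0.5, params) == pytest.approx(-0.09)

    def test_constant_force_strain(self, params):
        assert constant_force_strain(params.A0, params) == params.eps_s
        assert constant_force_strain(2.0, params) == pytest.approx(params.eps_s / 2)
        assert constant_force_strain(1e9, params) < 1e-8
        with pytest.raises(ValueError):
            constant_force_strain(0.0, params)

    def test_density_fixed_points_exact(self, params):
        # homeostasis: D0 at a=0 is an exact fixed point
        assert update_density(params.D0, 0.0, 2, 3, params) == params.D0
        # fully fibrotic: Dmax at a=a_fib stays at Dmax
        assert update_density(params.Dmax, params.a_fib, 2, 3, params) == params.Dmax

    def test_density_influx_only(self, params):
        d = update_density(0.0, 0.0, 2, 3, params)
        assert d == pytest.approx(params.p1 * (2 / 3), rel=1e-12)
        assert d > 0

    def test_death_and_division_response(self, params):
        assert death_probability(0.0, params) == pytest.approx(params.p2_0)
        assert death_probability(params.a_fib, params) == 0.0
        assert death_probability(-0.3, params) > params.p2_0
        assert division_probability(0.0, params) == 0.0
        assert division_probability(params.a_fib, params) == params.p3_max
        # no fibrotic density response below the critical weight
        p = replace(params, w2=0.3)
        assert p.a_fib < 0
        assert division_probability(0.2, p) == 0.0


class TestElementSimulation:
    def test_homeostasis_is_exact_fixed_point(self, params):
        traj = simulate_element(params, 1.0, n_iterations=200)
        for s in traj.states:
            assert (s.A, s.eps, s.a, s.D) == (1.0, 1.0, 0.0, 0.3)
        assert traj.outcome is Outcome.HEALING

    def test_constant_force_invariant(self, params):
        traj = simulate_element(replace(params, w2=2.0), 4.0, n_iterations=500)
        prod0 = traj.states[0].eps * traj.states[0].A
        for s in traj.states:
            assert s.eps * s.A == pytest.approx(prod0, rel=1e-9)

    def test_softening_heals(self):
        traj = simulate_element(replace(P, w2=1.5), 0.5)
        assert traj.outcome is Outcome.HEALING
        assert traj.final.A == pytest.approx(1.0, abs=0.01)

    def test_severe_stiffening_runs_away(self):
        traj = simulate_element(replace(P, w2=2.0), 50.0)
        assert traj.outcome is Outcome.FIBROTIC
        assert traj.final.A > traj.states[0].A
        assert traj.final.eps < 0.1          # strain collapses
        assert traj.final.D == pytest.approx(P.Dmax, rel=0.05)

    def test_bit_reproducible(self, params):
        t1 = simulate_element(replace(params, w2=2.0), 7.0, n_iterations=300)
        t2 = simulate_element(replace(params, w2=2.0), 7.0, n_iterations=300)
        assert [s.A for s in t1.states] == [s.A for s in t2.states]

    def test_classify_empty_rejected(self, params):
        from fibronet.core_dynamics import Trajectory
        with pytest.raises(ValueError):
            classify_outcome(Trajectory([]), params)


class TestThresholds:
    def test_subcritical_weight_never_fibrotic(self):
        assert find_fibrotic_threshold(replace(P, w2=0.4)) == math.inf
        # dense scan confirms: healing only
        p = replace(P, w2=0.4)
        outcomes = {simulate_element(p, m).outcome for m in multiplier_grid(p)}
        assert outcomes == {Outcome.HEALING}

    def test_threshold_decreases_with_stiffness_weight(self):
        ths = [find_fibrotic_threshold(replace(P, w2=w2))
               for w2 in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert all(b < a for a, b in zip(ths, ths[1:]))
        assert ths[1] < ths[0] < 20.0

    def test_threshold_matches_brute_force_scan(self):
        """Bisection agrees with an exhaustive multiplier scan at step 0.01."""
        p = replace(P, w2=1.5)
        th = find_fibrotic_threshold(p)
        # independent coarse-to-fine scan for the first fibrotic multiplier
        lo = 1.0
        m = lo
        while simulate_element(p, m).outcome is not Outcome.FIBROTIC:
            lo = m
            m += 0.5
        m = lo
        while simulate_element(p, m).outcome is not Outcome.FIBROTIC:
            m += 0.01
        assert th == pytest.approx(m, abs=0.02)

    def test_outcome_monotone_in_multiplier(self):
        """Healing multipliers form an interval below the fibrotic ones."""
        order = {Outcome.HEALING: 0, Outcome.UNDECIDED: 1, Outcome.FIBROTIC: 2}
        for w2 in (1.0, 2.0, 3.0):
            p = replace(P, w2=w2)
            seq = [order[simulate_element(p, m).outcome]
                   for m in np.arange(0.2, 15.0, 0.2)]
            assert seq == sorted(seq)

    def test_critical_weight(self):
        cw = find_critical_weight(P)
        assert cw == pytest.approx(0.5, abs=1e-3)

    def test_critical_weight_scales_with_strain_weight(self):
        cw2 = find_critical_weight(replace(P, w1=2.0))
        assert cw2 == pytest.approx(2.0 * find_critical_weight(P), rel=1e-3)


class TestPhaseDiagram:
    def test_steady_state_and_extremes(self, params):
        # a local grid around homeostasis: the center point heals
        near = phase_diagram([0.9, 1.0, 1.1], [0.9, 1.0, 1.1], params,
                             n_iterations=2000)
        assert near[1][1] == Outcome.HEALING.value       # (eps=1, A=1)
        # low strain far beyond the threshold area: fibrotic
        far = phase_diagram([0.05], [150.0], params, n_iterations=2000)
        assert far[0][0] == Outcome.FIBROTIC.value

    def test_boundary_on_constant_force_curve(self):
        """Along eps*A = eps_s*A0 the phase flips at the injury threshold."""
        p = replace(P, w2=2.0)
        th = find_fibrotic_threshold(p)
        below, above = th * 0.9, th * 1.2
        lab_b = phase_diagram([1.0 / below], [below], p)[0][0]
        lab_a = phase_diagram([1.0 / above], [above], p)[0][0]
        assert lab_b in (Outcome.HEALING.value, "mixed")
        assert lab_a in (Outcome.FIBROTIC.value, "mixed")


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"w1": -0.1}, {"At": 0.5}, {"eps_s": 0.0}, {"r": 1.5},
        {"p1": 2.0}, {"Dmax": 0.1}, {"E": 0.0}, {"beta": 0.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
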