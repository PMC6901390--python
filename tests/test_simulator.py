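"""Integration tests: event handling, conservation and solver cross-checks."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

import cascadekin as ck
from cascadekin.cascade_model import build_rate_system
from cascadekin.simulator import _integrate

from conftest import rk4_trajectory


class TestOnePot:
    def test_zero_loadings_keep_all_species_constant(self, onepot_recipe, params):
        tc = ck.simulate_onepot(
            onepot_recipe.scaled_loadings(0.0), np.linspace(0, 18, 19), params
        )
        assert np.allclose(tc.values, tc.values[:, :1])

    def test_standard_run_bounds(self, onepot_course):
        la = onepot_course.get("LA")
        man = onepot_course.get("MAN")
        assert 0 < la[-1] <= 5.0          # titre bounded by the 1:1 ceiling
        assert man[-1] < man[0]           # substrate is consumed
        assert np.all(onepot_course.values >= 0)

    def test_lactate_monotone_mannose_monotone(self, onepot_course):
        assert np.all(np.diff(onepot_course.get("LA")) >= -1e-9)
        assert np.all(np.diff(onepot_course.get("MAN")) <= 1e-9)

    def test_delayed_addition_rejected(self, sequential_recipe):
        with pytest.raises(ck.CascadeError):
            ck.simulate_onepot(sequential_recipe)

    def test_aldt_only_matches_closed_form_progress_curve(self, no_decay_params):
        # dehydrogenase alone: MAN follows the implicit MM progress curve
        # Km*ln(S0/S) + S0 - S = Vcap*t, solved here by root bracketing
        p = no_decay_params.updated(
            aux=ck.AuxRates(k_hyd_per_min=0.05, k_gaox=0.0), km_cofactor_mM=0.0
        )
        recipe = ck.ReactionRecipe.from_concentrations(
            {"MAN": 5.0, "NADp": 50.0}, [ck.Loading("AldT", 0.2)]
        )
        t_grid = np.linspace(0, 6, 25)
        tc = ck.simulate_onepot(
            recipe, t_grid, p, ck.SolverOptions(rtol=1e-11, atol=1e-13)
        )
        Km, S0, V = 9.73, 5.0, 0.2 * 60.0

        def closed_form(t):
            if t == 0:
                return S0
            return brentq(
                lambda S: Km * np.log(S0 / S) + S0 - S - V * t,
                1e-12, S0, xtol=1e-14, rtol=8.9e-16,
            )

        exact = np.array([closed_form(t) for t in t_grid])
        sim = tc.get("MAN")
        assert np.max(np.abs(sim - exact) / np.maximum(exact, 1e-12)) < 1e-6


class TestSequential:
    def test_event_at_zero_equals_onepot(self, onepot_recipe, params):
        grid = np.linspace(0, 6, 13)
        a = ck.simulate_onepot(onepot_recipe, grid, params)
        b = ck.simulate_sequential(onepot_recipe, grid, params)
        assert np.array_equal(a.values, b.values)

    def test_paper_schedule_phases(self, sequential_recipe, params):
        grid = ck.default_grid(18.5)
        tc = ck.simulate_sequential(sequential_recipe, grid, params)
        la, kdg = tc.get("LA"), tc.get("KDG")
        # no lactate before LDH enters at 17.5 h, positive at the end
        assert np.all(la[grid < 17.5] == 0.0)
        assert la[-1] > 0
        # KDG appears only after the dehydratase enters at 1.5 h and is
        # drawn down once the aldolase enters at 16.5 h
        assert np.all(kdg[grid <= 1.5] == 0.0)
        assert kdg[grid < 16.5].max() > 0.5
        i_kdga = np.searchsorted(grid, 16.5)
        assert kdg[-1] < kdg[i_kdga] / 2

    def test_cofactor_spike_steps_total(self, sequential_recipe, params):
        grid = ck.default_grid(18.5)
        tc = ck.simulate_sequential(sequential_recipe, grid, params)
        total = ck.nad_balance(tc)
        before = total[grid < 17.5]
        after = total[grid >= 17.5]
        assert np.allclose(before, 20.0, rtol=1e-6)
        assert np.allclose(after, 30.0, rtol=1e-6)

    def test_event_outside_grid_span_rejected(self, sequential_recipe, params):
        with pytest.raises(ck.CascadeError):
            ck.simulate_sequential(sequential_recipe, np.linspace(0, 10, 11), params)

    def test_trajectory_continuous_in_unspiked_species(self, sequential_recipe, params):
        grid = ck.default_grid(18.5)
        tc = ck.simulate_sequential(sequential_recipe, grid, params)
        # mannose shows no discontinuity at event times: the step across an
        # event is no larger than the neighbouring smooth-consumption steps
        man = tc.get("MAN")
        d = np.abs(np.diff(man))
        for ev in (1.5, 16.5, 17.5):
            i = np.searchsorted(grid, ev)
            local = max(d[max(i - 3, 0): i].max(), 1e-9)
            assert d[i - 1] <= 2.0 * local


class TestConservation:
    def test_carbon_constant_on_standard_run(self, onepot_course):
        cb = ck.carbon_balance(onepot_course)
        assert cb[0] == pytest.approx(30.0)  # 5 mM C6 sugar
        assert np.max(np.abs(cb - cb[0])) / cb[0] < 1e-6

    def test_cofactor_constant_on_standard_run(self, onepot_course):
        nb = ck.nad_balance(onepot_course)
        assert np.max(np.abs(nb - nb[0])) / nb[0] < 1e-6

    def test_manual_carbon_arithmetic(self):
        tc = ck.TimeCourse(
            times=np.array([0.0, 1.0]),
            values=np.array([[2.0, 2.0], [2.0, 2.0]]),
            species=("PYR", "GA"),
        )
        assert np.allclose(ck.carbon_balance(tc), 12.0)

    def test_relative_integral_input_rejected(self, onepot_course):
        rel = ck.normalize_timecourse(onepot_course)
        with pytest.raises(TypeError):
            ck.carbon_balance(rel)
        with pytest.raises(TypeError):
            ck.nad_balance(rel)

    def test_no_cofactor_balance_is_zero(self, onepot_recipe, params):
        recipe = replace(
            onepot_recipe, initial=ck.species_vector(MAN=5.0), spikes=()
        )
        tc = ck.simulate_onepot(recipe, np.linspace(0, 2, 5), params)
        assert np.allclose(ck.nad_balance(tc), 0.0)


class TestSolverCrossChecks:
    def test_time_rescaling_invariance(self, onepot_recipe, no_decay_params):
        """Doubling every rate (enzyme capacities and the first-order
        hydrolysis constant) and halving time leaves the path unchanged."""
        p1 = no_decay_params
        p2 = p1.updated(
            aux=replace(p1.aux, k_hyd_per_min=2 * p1.aux.k_hyd_per_min)
        )
        grid = np.linspace(0, 8, 17)
        a = ck.simulate_onepot(onepot_recipe, grid, p1)
        b = ck.simulate_onepot(onepot_recipe.scaled_loadings(2.0), grid / 2, p2)
        assert np.allclose(a.values, b.values, rtol=1e-6, atol=1e-8)

    def test_adaptive_agrees_with_fixed_step_rk4(self, onepot_recipe, params):
        grid = np.linspace(0, 18, 37)
        tc = ck.simulate_onepot(onepot_recipe, grid, params)
        rhs = build_rate_system(onepot_recipe, params)
        oracle = rk4_trajectory(rhs, onepot_recipe.initial, grid, dt=0.001)
        scale = np.maximum(np.abs(oracle), 1e-3)
        assert np.max(np.abs(tc.values - np.maximum(oracle, 0)) / scale) < 1e-4


class TestTimeCourse:
    def test_non_monotone_grid_rejected(self, onepot_recipe, params):
        with pytest.raises(ck.CascadeError):
            ck.simulate_onepot(onepot_recipe, np.array([0.0, 1.0, 0.5]), params)

    def test_absent_species_raises_keyerror(self, onepot_course):
        sub = onepot_course.subset(("MAN", "LA"))
        with pytest.raises(KeyError):
            sub.get("KDG")

    def test_tidy_round_shape(self, onepot_course):
        frame = onepot_course.to_tidy()
        assert set(frame.columns) == {"time_h", "species", "value", "kind", "replicate"}
        assert len(frame) == onepot_course.values.size
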