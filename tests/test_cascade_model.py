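"""Unit tests of the elementary rate laws and the assembled ODE system."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cascadekin as ck
from cascadekin.cascade_model import (
    CARBON,
    IDX,
    REACTIONS,
    SPECIES,
    build_rate_system,
    stoichiometric_matrix,
)


class TestMichaelisMenten:
    @pytest.mark.parametrize(
        "S, Km, Vcap, expected",
        [
            (9.73, 9.73, 0.2, 0.1),       # half-saturation
            (0.0, 9.73, 0.2, 0.0),        # no substrate
            (5.0, 9.73, 0.2, 0.06789),    # hand arithmetic 0.2*5/14.73
        ],
    )
    def test_examples(self, S, Km, Vcap, expected):
        assert ck.michaelis_menten_rate(S, Km, Vcap) == pytest.approx(
            expected, abs=1e-5
        )

    @pytest.mark.parametrize(
        "S, Km", [(-1.0, 9.73), (5.0, 0.0), (5.0, -2.0)]
    )
    def test_domain_errors(self, S, Km):
        with pytest.raises(ck.CascadeError):
            ck.michaelis_menten_rate(S, Km, 0.2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        s1=st.floats(0, 1e3),
        ds=st.floats(0, 1e3),
        km=st.floats(1e-3, 1e3),
        vcap=st.floats(0, 1e2),
    )
    def test_monotone_and_bounded(self, s1, ds, km, vcap):
        v1 = ck.michaelis_menten_rate(s1, km, vcap)
        v2 = ck.michaelis_menten_rate(s1 + ds, km, vcap)
        assert 0 <= v1 <= v2 <= vcap


class TestAldolAddition:
    @pytest.mark.parametrize(
        "pyr, ga, km, vcap, expected",
        [
            (0.0, 10.0, 8.07, 0.4, 0.0),      # missing co-substrate
            (8.07, 8.07, 8.07, 0.4, 0.1),     # both at Km: each factor 1/2
            (5.0, 5.0, 8.07, 0.4, 0.0585),    # hand arithmetic 0.4*25/13.07^2
        ],
    )
    def test_examples(self, pyr, ga, km, vcap, expected):
        assert ck.aldol_addition_rate(pyr, ga, km, vcap) == pytest.approx(
            expected, abs=1e-4
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(pyr=st.floats(0, 100), ga=st.floats(0, 100))
    def test_symmetric_in_substrates(self, pyr, ga):
        a = ck.aldol_addition_rate(pyr, ga, 8.07, 0.4)
        b = ck.aldol_addition_rate(ga, pyr, 8.07, 0.4)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-15)


class TestEquilibriumConstant:
    def test_zero_dG_gives_unity(self):
        assert ck.equilibrium_constant_from_dG(0.0, 323.0) == 1.0

    def test_large_dG_vanishes(self):
        assert ck.equilibrium_constant_from_dG(500.0, 323.0) < 1e-60

    def test_cleavage_value(self):
        # exp(-6200 J / (8.314 J/mol/K * 323 K)) computed independently
        keq = ck.equilibrium_constant_from_dG(6.2, 323.0)
        assert keq == pytest.approx(0.0992, abs=2e-4)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ck.CascadeError):
            ck.equilibrium_constant_from_dG(6.2, 0.0)


class TestNetAldol:
    def test_all_zero_is_zero(self, params):
        v = ck.net_aldol_rate(0, 0, 0, vcap=0.4, km_comb=8.07, thermo=params.thermo)
        assert v == 0.0

    def test_zero_exactly_at_equilibrium(self, params):
        keq_mM = ck.equilibrium_constant_from_dG(6.2, 323.0) * 1000
        kdg = 1.0
        x = math.sqrt(keq_mM * kdg)  # pyr*ga/kdg == Keq
        v = ck.net_aldol_rate(kdg, x, x, vcap=0.4, km_comb=8.07, thermo=params.thermo)
        assert v == pytest.approx(0.0, abs=1e-12)

    def test_sign_change_across_equilibrium(self, params):
        keq_mM = ck.equilibrium_constant_from_dG(6.2, 323.0) * 1000
        kdg = 2.0
        x = math.sqrt(keq_mM * kdg)
        below = ck.net_aldol_rate(
            kdg, 0.9 * x, x, vcap=0.4, km_comb=8.07, thermo=params.thermo
        )
        above = ck.net_aldol_rate(
            kdg, 1.1 * x, x, vcap=0.4, km_comb=8.07, thermo=params.thermo
        )
        assert below > 0 > above  # cleavage below equilibrium, addition above

    def test_irreversible_limit_is_mm_in_kdg(self, params):
        v = ck.net_aldol_rate(
            3.0, 5.0, 5.0, vcap=0.4, km_comb=8.07, thermo=params.thermo, reverse=False
        )
        assert v == pytest.approx(ck.michaelis_menten_rate(3.0, 8.07, 0.4))

    def test_forward_limit_matches_mm(self, params):
        v = ck.net_aldol_rate(3.0, 0.0, 0.0, vcap=0.4, km_comb=8.07, thermo=params.thermo)
        assert v == pytest.approx(ck.michaelis_menten_rate(3.0, 8.07, 0.4), rel=1e-12)


class TestActiveCapacity:
    def test_initial_and_half_life(self):
        assert ck.active_capacity(0.2, 9.8, 0.0) == 0.2
        assert ck.active_capacity(0.2, 9.8, 9.8) == pytest.approx(0.1)

    def test_long_incubation_fraction(self):
        # 2^(-20/9.8) = 24.3% of the initial loading after 20 h
        frac = ck.active_capacity(1.0, 9.8, 20.0)
        assert frac == pytest.approx(0.243, abs=1e-3)

    def test_infinite_half_life_is_constant(self):
        for t in (0.0, 5.0, 100.0):
            assert ck.active_capacity(11.6, math.inf, t) == 11.6

    def test_negative_time_rejected(self):
        with pytest.raises(ck.CascadeError):
            ck.active_capacity(0.2, 9.8, -1.0)


class TestLactoneHydrolysis:
    @pytest.mark.parametrize(
        "ml, k, expected", [(0.0, 0.05, 0.0), (2.0, 0.0, 0.0), (2.0, 0.05, 0.1)]
    )
    def test_examples(self, ml, k, expected):
        assert ck.lactone_hydrolysis_rate(ml, k) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ck.CascadeError):
            ck.lactone_hydrolysis_rate(-1.0, 0.05)


class TestRateSystem:
    def test_carbon_row_of_stoichiometry_is_null(self):
        # every reaction conserves carbon: 6->6, 6->3+3, 3->3
        N = stoichiometric_matrix()
        assert np.allclose(CARBON @ N, 0.0)
        assert N.shape == (len(SPECIES), len(REACTIONS))

    def test_cofactor_row_of_stoichiometry_is_null(self):
        N = stoichiometric_matrix()
        nad_total = np.zeros(len(SPECIES))
        nad_total[IDX["NADp"]] = nad_total[IDX["NADH"]] = 1.0
        assert np.allclose(nad_total @ N, 0.0)

    def test_zero_loadings_give_zero_derivative(self, params, onepot_recipe):
        recipe = onepot_recipe.scaled_loadings(0.0)
        rhs = build_rate_system(recipe, params)
        dy = rhs(1.0, recipe.initial)
        assert np.allclose(dy, 0.0)

    def test_conservation_of_random_states(self, params, onepot_recipe):
        rhs = build_rate_system(onepot_recipe, params)
        rng = np.random.default_rng(7)
        for _ in range(20):
            y = rng.uniform(0, 10, len(SPECIES))
            t = rng.uniform(0, 18)
            dy = rhs(t, y)
            assert CARBON @ dy == pytest.approx(0.0, abs=1e-10)
            assert dy[IDX["NADp"]] + dy[IDX["NADH"]] == pytest.approx(0.0, abs=1e-12)

    def test_mannose_flux_bounded_by_decayed_capacity(self, params, onepot_recipe):
        rhs = build_rate_system(onepot_recipe, params)
        y = ck.species_vector(MAN=500.0, NADp=500.0)  # deep saturation
        for t in (0.0, 5.0, 10.0):
            v_man = -rhs(t, y)[IDX["MAN"]] / 60.0  # back to mM/min
            cap = ck.active_capacity(0.2, 9.8, t)
            assert 0 <= v_man <= cap + 1e-12

    def test_unknown_enzyme_rejected(self, params, onepot_recipe):
        bad = {k: v for k, v in params.enzymes.items() if k != "LDH"}
        with pytest.raises(ck.CascadeError):
            build_rate_system(onepot_recipe, params.updated(enzymes=bad))


class TestSpeciesVector:
    def test_unknown_species_rejected(self):
        with pytest.raises(ck.CascadeError):
            ck.species_vector(XYZ=1.0)

    def test_negative_rejected(self):
        with pytest.raises(ck.CascadeError):
            ck.species_vector(MAN=-1.0)

    def test_canonical_order(self):
        y = ck.species_vector(MAN=5.0, NADp=5.0)
        assert y[0] == 5.0 and y[IDX["NADp"]] == 5.0 and y.sum() == 10.0
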