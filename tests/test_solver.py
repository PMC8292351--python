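"""Steady-state solution: regimes, back-solves, and regulatory modes."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cb6f.light_reactions import PhotochemicalConstants, _phi_p2
from cb6f.solver import (
    LeafParameters,
    ac,
    aj,
    light_saturation_point,
    solve_cross_sections,
    solve_npq,
    solve_steady_state,
)
from cb6f.stoichiometry import (
    co2_compensation,
    demand_fluxes,
    eta,
    rubisco_specificity,
    supply_fluxes,
    Environment,
)


class TestLimitingRates:
    def test_aj_worked_chain(self, leaf, env):
        a_j, jp680, jp700 = aj(2400.0, leaf, env)
        assert jp700 == pytest.approx(255.4, abs=0.1)
        assert jp680 == pytest.approx(246.9, abs=0.1)
        assert a_j == pytest.approx(35.3, abs=0.05)

    def test_aj_dark(self, leaf, env):
        a_j, _, _ = aj(0.0, leaf, env)
        assert a_j == pytest.approx(-leaf.r_d)

    def test_aj_asymptote(self, leaf, env, eta_ref, gamma_star):
        a_j, _, _ = aj(1e9, leaf, env)
        x = gamma_star / env.c
        expected = (leaf.v_max_cb6f / eta_ref) / (4 + 8 * x) * (1 - x) - leaf.r_d
        assert a_j == pytest.approx(expected, rel=1e-6)

    def test_ac_reference(self, leaf, env):
        a_c, v_c = ac(leaf, env)
        assert v_c == pytest.approx(26.19, abs=0.01)
        assert a_c == pytest.approx(20.22, abs=0.01)

    def test_ac_limits(self, leaf, gamma_star):
        a_c, _ = ac(leaf, Environment(c=1e9))
        assert a_c == pytest.approx(leaf.v_max_rubc - leaf.r_d, rel=1e-5)
        a_c, _ = ac(leaf, Environment(c=gamma_star))
        assert a_c == pytest.approx(-leaf.r_d, abs=1e-9)


class TestSolveNpq:
    def test_zero_when_target_equals_supply(self, k):
        f2 = 0.3
        supply = 500.0 * 0.44 * _phi_p2(f2, 0.0, k, 0.0)
        k_n2, flag = solve_npq(supply, 500.0, 0.44, f2, k)
        assert k_n2 == pytest.approx(0.0, abs=1e-9)
        assert not flag

    def test_saturating_light_reference(self, k):
        k_n2, flag = solve_npq(144.53, 2400.0, 0.44, 0.7297, k)
        assert k_n2 == pytest.approx(3.79, abs=0.01)
        assert not flag

    @pytest.mark.parametrize("u", [0.0, 1.0, 2.0, 8.0])
    def test_against_brent_root_oracle(self, u, rng):
        """The closed-form quadratic root matches a bracketed scalar
        root-find of the same yield balance, across random states."""
        k = PhotochemicalConstants(k_u2=u)
        for _ in range(30):
            q = rng.uniform(100.0, 2400.0)
            a2 = rng.uniform(0.3, 0.5)
            f2 = rng.uniform(0.05, 0.95)
            supply0 = q * a2 * _phi_p2(f2, 0.0, k, u)
            target = supply0 * rng.uniform(0.2, 0.999)
            k_n2, flag = solve_npq(target, q, a2, f2, k)
            assert not flag
            oracle = brentq(
                lambda n: q * a2 * _phi_p2(f2, n, k, u) - target,
                0.0, 1000.0, xtol=1e-12, rtol=1e-14,
            )
            assert k_n2 == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_infeasible_target_flagged(self, k):
        k_n2, flag = solve_npq(1000.0, 100.0, 0.44, 0.9, k)
        assert flag and k_n2 == 0.0


class TestCrossSections:
    def test_reference_split(self, eta_ref):
        k0 = PhotochemicalConstants(k_u2=0.0)
        a1, a2 = solve_cross_sections(eta_ref, 0.0, k0, 0.85)
        assert a2 == pytest.approx(0.4358, abs=2e-4)
        assert a1 == pytest.approx(0.4142, abs=2e-4)

    def test_split_independent_of_closure_without_sharing(self, eta_ref):
        k0 = PhotochemicalConstants(k_u2=0.0)
        for f in (0.0, 0.3, 0.7):
            _, a2 = solve_cross_sections(eta_ref, f, k0, 0.85)
            assert a2 == pytest.approx(0.4358, abs=2e-4)

    def test_state_transition_decreases(self, eta_ref):
        """K_U2=2 at the saturation closure drops α2 by ≈17 % from dark;
        the lake limit gives ≈22–23 %."""
        f_sat = 0.42713  # η·J_P680(rubisco)/V_max at reference conditions
        k2 = PhotochemicalConstants(k_u2=2.0)
        _, a2_dark = solve_cross_sections(eta_ref, 0.0, k2, 0.85)
        _, a2_sat = solve_cross_sections(eta_ref, f_sat, k2, 0.85)
        assert 100.0 * (1 - a2_sat / a2_dark) == pytest.approx(16.6, abs=0.2)
        k_inf = PhotochemicalConstants(k_u2=1e8)
        _, a2_lake = solve_cross_sections(eta_ref, f_sat, k_inf, 0.85)
        assert 100.0 * (1 - a2_lake / a2_dark) == pytest.approx(22.8, abs=0.3)


class TestLightSaturation:
    def test_reference_value(self, leaf, env):
        assert light_saturation_point(leaf, env) == pytest.approx(663.0, abs=0.5)

    def test_never_saturates(self, leaf, env):
        big = leaf.with_(v_max_rubc=10000.0)
        assert light_saturation_point(big, env) == np.inf

    def test_continuity_of_min_rule(self, leaf, env):
        q_sat = light_saturation_point(leaf, env)
        lo = solve_steady_state(q_sat - 1e-6, leaf, env)
        hi = solve_steady_state(q_sat + 1e-6, leaf, env)
        assert lo.a == pytest.approx(hi.a, abs=1e-6)
        assert lo.regime == "b6f_limited" and hi.regime == "rubisco_limited"


class TestSteadyState:
    def test_saturating_light_worked_chain(self, leaf, env):
        st = solve_steady_state(2400.0, leaf, env)
        assert st.regime == "rubisco_limited"
        assert st.j_p680 == pytest.approx(144.5, abs=0.1)
        assert st.j_p700 == pytest.approx(149.5, abs=0.1)
        assert st.f2 == pytest.approx(0.730, abs=1e-3)
        assert st.k_star_over_kq == pytest.approx(0.585, abs=1e-3)
        assert st.k_n2 == pytest.approx(3.79, abs=0.01)

    def test_limiting_light(self, leaf, env):
        st = solve_steady_state(300.0, leaf, env)
        assert st.regime == "b6f_limited"
        assert st.k_star_over_kq == 1.0
        assert st.f2 == pytest.approx(0.2523, abs=1e-4)
        assert st.f1 == pytest.approx(st.f2, abs=1e-12)
        assert st.fb == st.f2

    def test_dark(self, leaf, env):
        st = solve_steady_state(0.0, leaf, env)
        assert st.a == pytest.approx(-leaf.r_d)
        assert st.f1 == st.f2 == st.fb == 0.0
        assert st.k_n2 == 0.0

    def test_minimum_rule_continuous_nondecreasing(self, leaf, env):
        qs = np.linspace(0.0, 2400.0, 121)
        a = np.array([solve_steady_state(q, leaf, env).a for q in qs])
        aj_ac = np.array(
            [min(aj(q, leaf, env)[0], ac(leaf, env)[0]) for q in qs]
        )
        np.testing.assert_allclose(a, aj_ac, atol=1e-9)
        assert np.all(np.diff(a) >= -1e-9)

    def test_photosynthetic_control_bounds(self, leaf, env):
        q_sat = light_saturation_point(leaf, env)
        qs = np.linspace(50.0, 2400.0, 60)
        ks = np.array([solve_steady_state(q, leaf, env).k_star_over_kq for q in qs])
        assert np.all((ks > 0) & (ks <= 1.0))
        below = qs < q_sat
        assert np.all(ks[below] == 1.0)
        above = ks[~below]
        assert np.all(np.diff(above) < 0)

    @pytest.mark.parametrize("cef_mode", ["minimal", "regulatory"])
    def test_cb6f_flux_bracket(self, cef_mode, env):
        """η·J_P680 ≤ J_CB6F ≤ J'_CB6F in both CEF1 modes."""
        leaf = LeafParameters(cef_mode=cef_mode)
        for q in (100.0, 400.0, 663.0, 1000.0, 2400.0):
            st = solve_steady_state(q, leaf, env)
            j_prime = aj(q, leaf, env)[2]
            assert st.eta * st.j_p680 <= st.j_cb6f * (1 + 1e-9)
            assert st.j_cb6f <= j_prime * (1 + 1e-9)

    def test_budget_closure_at_solved_states(self, leaf, env, coupling):
        for q in np.linspace(0.0, 2400.0, 25):
            st = solve_steady_state(q, leaf, env)
            m = demand_fluxes(st.v_c, st.v_o)
            reductant, atp = supply_fluxes(st.j_p680, st.j_p700, coupling)
            assert atp == pytest.approx(m.j_atp, rel=1e-10, abs=1e-10)
            assert reductant == pytest.approx(
                m.j_fd + 2 * m.j_nadph, rel=1e-10, abs=1e-10
            )

    def test_regulatory_mode_keeps_kstar_maximal(self, env):
        leaf = LeafParameters(cef_mode="regulatory")
        st = solve_steady_state(2400.0, leaf, env)
        assert st.regime == "rubisco_limited"
        assert st.k_star_over_kq == 1.0
        assert st.f1 == pytest.approx(st.f2, abs=1e-9)  # closures stay balanced
        assert st.cef1 > solve_steady_state(2400.0, LeafParameters(), env).cef1

    def test_case7_case8_same_assimilation(self, env):
        for q in (200.0, 800.0, 1600.0, 2400.0):
            a7 = solve_steady_state(q, LeafParameters(), env).a
            a8 = solve_steady_state(q, LeafParameters(cef_mode="regulatory"), env).a
            assert a7 == pytest.approx(a8, rel=1e-12)

    def test_no_npq_mode_has_zero_kn2(self, env):
        leaf = LeafParameters(npq_enabled=False)
        for q in (300.0, 1000.0, 2400.0):
            st = solve_steady_state(q, leaf, env)
            assert st.k_n2 == 0.0

    def test_npq_only_mode_keeps_kstar_maximal(self, env):
        leaf = LeafParameters(b6f_control=False)
        st = solve_steady_state(2400.0, leaf, env)
        assert st.k_star_over_kq == 1.0
        assert st.k_n2 > 0
        # PQ pool poised below the Eq-34 value: NPQ absorbs all control
        assert st.fb < solve_steady_state(2400.0, LeafParameters(), env).fb

    def test_psii_limited_fallback_flagged(self, env):
        """A tiny PS II cross-section cannot feed the b6f-limited flux at
        K_N2=0; the solver falls back to a flagged self-consistent closure."""
        leaf = LeafParameters(alpha_2=0.10, alpha_1=0.75)
        st = solve_steady_state(500.0, leaf, env)
        assert "psii_limited" in st.flags
        assert 0.0 <= st.f2 <= 1.0
        assert st.k_n2 == 0.0

    def test_constant_transition_poise_under_joint_scaling(self, env):
        """Scaling V_max(CB6F) and V_max(RUBC) together leaves the PQ-pool
        poise at the light-saturation point unchanged."""
        k2 = PhotochemicalConstants(k_u2=2.0)
        poises = []
        for s in (0.5, 1.0, 2.0):
            leaf = LeafParameters(
                v_max_cb6f=350.0 * s, v_max_rubc=100.0 * s, state_transitions=True
            )
            q_sat = light_saturation_point(leaf, env, k2)
            st = solve_steady_state(q_sat, leaf, env, k2)
            poises.append(st.fb)
        assert np.ptp(poises) < 1e-8


class TestGridOracle:
    def _oracle(self, q, leaf, env, k, kin, coupling):
        """Brute-force simultaneous nested-grid search over (f2, K_N2)
        minimizing the flux-balance residuals."""
        gamma = co2_compensation(rubisco_specificity(kin), env.o)
        x = gamma / env.c
        e = eta(coupling, gamma, env.c)
        slope = leaf.alpha_1 * k.phi_p1_max
        f_poise = q / (leaf.v_max_cb6f / slope + q)
        v_c = leaf.v_max_rubc * env.c / (
            kin.km_c * (1 + env.o / kin.km_o) + env.c
        )
        target = min(f_poise * leaf.v_max_cb6f / e, v_c * (4 + 8 * x))
        lo_f, hi_f, lo_n, hi_n = 0.0, 1.0, 0.0, 60.0
        f0 = n0 = None
        for _ in range(6):
            fs = np.linspace(lo_f, hi_f, 61)
            ns = np.linspace(lo_n, hi_n, 61)
            fg, ng = np.meshgrid(fs, ns)
            supply = q * leaf.alpha_2 * _phi_p2(fg, ng, k, k.k_u2)
            resid = ((supply - target) / max(target, 1.0)) ** 2 + (
                fg - f_poise
            ) ** 2
            i = np.unravel_index(np.argmin(resid), resid.shape)
            f0, n0 = fg[i], ng[i]
            df = 3.0 * (hi_f - lo_f) / 60.0
            dn = 3.0 * (hi_n - lo_n) / 60.0
            lo_f, hi_f = max(0.0, f0 - df), min(1.0, f0 + df)
            lo_n, hi_n = max(0.0, n0 - dn), min(60.0, n0 + dn)
        return f0, n0, target

    def test_agreement_on_random_parameterizations(self, kin, coupling, rng):
        from cb6f.light_reactions import DEFAULT_CONSTANTS

        checked = 0
        while checked < 20:
            a2 = rng.uniform(0.35, 0.5)
            leaf = LeafParameters(
                alpha_2=a2,
                alpha_1=0.85 - a2,
                v_max_cb6f=rng.uniform(200.0, 600.0),
                v_max_rubc=rng.uniform(60.0, 180.0),
            )
            env = Environment(c=rng.uniform(150.0, 800.0))
            q = rng.uniform(100.0, 2300.0)
            st = solve_steady_state(q, leaf, env)
            if st.flags:
                continue
            f0, n0, target = self._oracle(
                q, leaf, env, DEFAULT_CONSTANTS, kin, coupling
            )
            assert st.f2 == pytest.approx(f0, abs=2e-6)
            assert st.k_n2 == pytest.approx(n0, abs=5e-5)
            assert st.j_p680 == pytest.approx(target, rel=1e-6)
            checked += 1


def test_leaf_parameter_validation():
    with pytest.raises(ValueError):
        LeafParameters(alpha_2=0.5, alpha_1=0.5)  # sum != alpha_total
    with pytest.raises(ValueError):
        LeafParameters(cef_mode="bogus")
    derived = LeafParameters(alpha_2=0.5, alpha_1=None)
    assert derived.alpha_1 == pytest.approx(0.35)
    assert LeafParameters(v_max_rubc=200.0).r_d == pytest.approx(2.0)
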