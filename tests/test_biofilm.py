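"""Biofilm kinetics, steady-state solver and multiplicity scan."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofiltersim import (
    BiofilmState,
    average_rate,
    biofilm_rhs,
    build_grid,
    haldane_rate,
    interface_flux,
    multiplicity_scan,
    solve_biofilm_steady,
)

import oracles


class TestHaldaneRate:
    def test_zero_and_negative(self, params_two_states):
        kin = params_two_states.kinetics
        assert haldane_rate(0.0, kin) == 0.0
        with pytest.raises(ValueError):
            haldane_rate(-0.1, kin)

    def test_reference_values(self, params_two_states):
        kin = params_two_states.kinetics
        c_peak = math.sqrt(kin.k_s * kin.k_i)
        assert c_peak == pytest.approx(0.36742, rel=1e-4)
        assert haldane_rate(c_peak, kin) == pytest.approx(2.3581e4, rel=1e-4)
        assert haldane_rate(kin.k_s, kin) == pytest.approx(1.4862e4, rel=1e-4)

    def test_peak_is_global_maximum(self, params_two_states):
        kin = params_two_states.kinetics
        c = np.linspace(0.0, 50.0, 20001)
        r = haldane_rate(c, kin)
        c_star = c[np.argmax(r)]
        assert c_star == pytest.approx(kin.c_peak, abs=5e-3)
        assert np.max(r) <= haldane_rate(kin.c_peak, kin) + 1e-9

    @given(
        c1=st.floats(0.001, 60.0),
        c2=st.floats(0.001, 60.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_up_then_down(self, c1, c2, params_two_states):
        """Strictly increasing below sqrt(K_s K_I), strictly decreasing above."""
        kin = params_two_states.kinetics
        lo, hi = sorted((c1, c2))
        if lo == hi:
            return
        peak = kin.c_peak
        if hi <= peak:
            assert haldane_rate(lo, kin) < haldane_rate(hi, kin)
        elif lo >= peak:
            assert haldane_rate(lo, kin) > haldane_rate(hi, kin)


class TestBiofilmRhs:
    def test_uniform_profile_no_reaction_is_stationary(self, params_two_states):
        from dataclasses import replace

        p = params_two_states
        p0 = p.with_(kinetics=replace(p.kinetics, v_max=1e-300))
        g = build_grid(p.discretization.n_biofilm - 2)
        cs = 2.5 / p.transport.henry_h
        state = BiofilmState(c_profile=np.full(g.n_nodes, cs), thickness_l=1e-5)
        dc = biofilm_rhs(state, 2.5, p0, g)
        assert np.max(np.abs(dc)) < 1e-6

    def test_surface_value_pinned_by_henrys_law(self, params_two_states):
        # c_gas = 2.5 with H = 0.25 pins the interface at 10 g/m3
        p = params_two_states
        st_ = solve_biofilm_steady(2.5, 1e-6, p)
        assert st_.c_profile[-1] == pytest.approx(10.0, rel=1e-12)

    def test_degenerate_film_rejected(self, params_two_states):
        g = build_grid(3)
        state = BiofilmState(c_profile=np.zeros(g.n_nodes), thickness_l=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            biofilm_rhs(state, 1.0, params_two_states, g)

    def test_steady_solution_is_stationary(self, params_two_states):
        p = params_two_states
        st_ = solve_biofilm_steady(3.0, 2e-5, p)
        dc = biofilm_rhs(st_, 3.0, p)
        # residual scaled by the reaction magnitude
        assert np.max(np.abs(dc)) < 1e-4 * haldane_rate(p.kinetics.c_peak, p.kinetics)


class TestAverageRate:
    def test_uniform_profile_equals_pointwise_rate(self, params_two_states):
        kin = params_two_states.kinetics
        g = build_grid(8)
        state = BiofilmState(c_profile=np.full(g.n_nodes, 0.2), thickness_l=1e-5)
        assert average_rate(state, kin, g) == pytest.approx(
            haldane_rate(0.2, kin), rel=1e-12
        )

    def test_zero_profile(self, params_two_states):
        g = build_grid(8)
        state = BiofilmState(c_profile=np.zeros(g.n_nodes), thickness_l=1e-5)
        assert average_rate(state, params_two_states.kinetics, g) == 0.0

    def test_linear_profile_matches_dense_trapezoid(self, params_two_states):
        kin = params_two_states.kinetics
        g = build_grid(8)
        state = BiofilmState(c_profile=0.1 * g.nodes, thickness_l=1e-5)
        x = np.linspace(0, 1, 10001)
        dense = np.trapezoid(oracles.haldane(0.1 * x, kin), x)
        assert average_rate(state, kin, g) == pytest.approx(dense, rel=5e-3)


class TestSteadySolver:
    def test_no_reaction_gives_uniform_profile(self, params_two_states):
        from dataclasses import replace

        p = params_two_states
        p0 = p.with_(kinetics=replace(p.kinetics, v_max=1e-300))
        st_ = solve_biofilm_steady(2.0, 1e-5, p0)
        assert st_.c_profile == pytest.approx(np.full(st_.c_profile.size, 8.0), rel=1e-8)

    def test_first_order_regime_matches_cosh_solution(self, params_two_states):
        """At c << K_s*H the kinetics are first order and the profile is
        cosh(phi x)/cosh(phi) * c_gas/H with phi = L sqrt(k1/D)."""
        from dataclasses import replace

        p = params_two_states
        p = p.with_(discretization=replace(p.discretization, n_biofilm=18))
        kin, tr = p.kinetics, p.transport
        c_gas = 1e-4
        thickness = 1e-5  # phi ~ 10: resolved boundary layer
        k1 = kin.v_max * kin.rho_bio / kin.k_s
        phi = thickness * math.sqrt(k1 / tr.diffusivity_d)
        st_ = solve_biofilm_steady(c_gas, thickness, p)
        g = build_grid(p.discretization.n_biofilm - 2)
        analytic = np.cosh(phi * g.nodes) / math.cosh(phi) * c_gas / tr.henry_h
        assert np.max(np.abs(st_.c_profile - analytic)) < 0.01 * analytic.max()

    def test_profiles_monotone_nondecreasing(self, params_two_states):
        for cg in (0.5, 3.0, 8.0):
            st_ = solve_biofilm_steady(cg, 3e-5, params_two_states)
            assert np.all(np.diff(st_.c_profile) > -1e-6 * st_.c_profile.max())

    def test_flux_balances_integrated_consumption(self, params_two_states):
        p = params_two_states
        g = build_grid(p.discretization.n_biofilm - 2)
        st_ = solve_biofilm_steady(2.0, 2e-5, p)
        flux = interface_flux(st_.c_profile, st_.thickness_l, p.transport.diffusivity_d, g)
        consumed = st_.thickness_l * average_rate(st_, p.kinetics, g)
        assert flux == pytest.approx(consumed, rel=5e-3)

    def test_distinct_roots_from_different_guesses(self, params_two_states):
        """In the multiplicity window multi-start finds both stable states,
        and the converged root follows the seed it started from."""
        from biofiltersim import steady_states

        p = params_two_states
        thickness = 5e-5
        cg = 6.5  # inside the window mapped by the multiplicity scan
        roots = steady_states(cg, thickness, p)
        assert len(roots) >= 2
        depleted, saturated = roots[0], roots[-1]
        assert saturated.c_profile[0] > 10 * max(depleted.c_profile[0], 1e-6)
        # re-solving from each converged profile stays on that root
        again = solve_biofilm_steady(cg, thickness, p, initial_guess=depleted.c_profile)
        assert again.c_profile == pytest.approx(depleted.c_profile, abs=1e-6)

    def test_invalid_inputs(self, params_two_states):
        with pytest.raises(ValueError):
            solve_biofilm_steady(-1.0, 1e-5, params_two_states)
        with pytest.raises(ValueError):
            solve_biofilm_steady(1.0, 0.0, params_two_states)


class TestAgainstFiniteDifferenceOracle:
    @pytest.mark.parametrize("c_gas", [0.05, 0.5, 2.0, 10.0])
    def test_unique_state_flux_matches(self, c_gas, params_two_states):
        from dataclasses import replace

        p = params_two_states
        p = p.with_(discretization=replace(p.discretization, n_biofilm=22))
        thickness = 2e-5
        g = build_grid(p.discretization.n_biofilm - 2)
        roots = oracles.fd_multistart(c_gas, thickness, p)
        st_ = solve_biofilm_steady(c_gas, thickness, p)
        flux = interface_flux(st_.c_profile, thickness, p.transport.diffusivity_d, g)
        fd_fluxes = [f for _, _, f in roots]
        assert min(abs(flux - f) / f for f in fd_fluxes) < 0.01


class TestMultiplicityScan:
    def test_thin_film_single_branch(self, params_two_states):
        res = multiplicity_scan(np.linspace(0.5, 10, 12), 1e-6, params_two_states)
        assert res.window is None
        counts = res.to_frame().groupby("c_gas").size()
        assert (counts == 1).all()

    def test_thick_film_has_hysteresis_window(self, params_two_states):
        res = multiplicity_scan(np.linspace(2, 12, 21), 5e-5, params_two_states)
        assert res.window is not None
        lo, hi = res.window
        assert lo < hi
        labels = set(b.branch_label for b in res.branches)
        assert {"high_activity", "low_activity"} <= labels
        # inside the window the high branch carries more flux
        for cg in sorted({b.c_gas for b in res.branches}):
            here = [b for b in res.branches if b.c_gas == cg]
            if len(here) > 1:
                hi_b = [b for b in here if b.branch_label == "high_activity"]
                lo_b = [b for b in here if b.branch_label == "low_activity"]
                assert hi_b and lo_b
                assert hi_b[0].interface_flux > lo_b[0].interface_flux

    def test_branch_counts_agree_with_fd_multistart(self, params_two_states):
        p = params_two_states
        thickness = 5e-5
        res = multiplicity_scan(np.linspace(3, 10, 15), thickness, p)
        for cg in (4.0, 6.5, 9.5):
            fd_n = len(oracles.fd_multistart(cg, thickness, p))
            scan_n = sum(
                1
                for b in res.branches
                if abs(b.c_gas - cg) < 1e-9 and b.branch_label != "intermediate"
            )
            assert scan_n == fd_n

    def test_mature_film_window_covers_observed_transition_band(self, params_two_states):
        """At the thickness a nitrogen-limited mature film reaches
        (X ~ 5.6 g/kg, L ~ 5.9e-5 m), the hysteresis window spans the
        7.7-8.5 g/m3 band where the high-to-low activity transition is
        observed."""
        from dataclasses import replace

        p = params_two_states.with_(
            discretization=replace(params_two_states.discretization, n_biofilm=16)
        )
        res = multiplicity_scan(np.linspace(3.0, 13.0, 21), 5.9e-5, p)
        assert res.window is not None
        lo, hi = res.window
        assert lo < 7.7 and hi > 8.5

    def test_stability_labels_mark_middle_branch_intermediate(self, params_two_states):
        """Inside the window, time-relaxation labels the extreme branches
        stable and any middle root intermediate."""
        from dataclasses import replace

        p = params_two_states.with_(
            discretization=replace(params_two_states.discretization, n_biofilm=16)
        )
        res = multiplicity_scan(
            np.linspace(7.0, 8.0, 3), 5.9e-5, p, label_stability=True
        )
        labels = {}
        for b in res.branches:
            labels.setdefault(b.c_gas, []).append(b.branch_label)
        multi = [v for v in labels.values() if len(v) >= 2]
        assert multi, "no multiplicity found inside the window"
        for v in multi:
            assert "high_activity" in v and "low_activity" in v
        assert any("intermediate" in v for v in labels.values())

    def test_invalid_range(self, params_two_states):
        with pytest.raises(ValueError):
            multiplicity_scan([], 1e-5, params_two_states)
        with pytest.raises(ValueError):
            multiplicity_scan([2.0, 1.0], 1e-5, params_two_states)
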