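"""The 20-state kinetic scheme: construction, ODE, SSA, summary statistics."""

import math

import numpy as np
import pytest

from ampar_mwc.core import state_fractions
from ampar_mwc.kinetics import (
    DEFAULT_KON,
    GLUA3_GLUK2_ANCHORS,
    build_scheme,
    koff_from_K,
    ode_timecourse,
    rise_time_20_80,
    scale_conformational_rate,
    ssa_occupancy_average,
    ssa_timecourse,
    steady_state,
    time_to_fraction_of_steady_state,
    time_to_occupancy,
)


class TestRateInference:
    @pytest.mark.parametrize(
        "K, kon, expected",
        [(3.330e-6, 5e6, 16.65), (5.407e-5, 5e6, 270.35), (1.0, 1.0, 1.0)],
    )
    def test_koff_from_K(self, K, kon, expected):
        assert koff_from_K(K, kon) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            koff_from_K(0.0, 5e6)
        with pytest.raises(ValueError):
            koff_from_K(1e-5, -1.0)

    def test_fully_liganded_anchor_unscaled(self):
        assert scale_conformational_rate(3e5, 0.0601, 4, "forward") == 3e5

    def test_forward_scaling_two_ligands_removed_squares_c(self):
        got = scale_conformational_rate(3e5, 0.0601, 0, "forward", a=0.5)
        assert got == pytest.approx(3e5 * 0.0601**2, rel=1e-12)  # ~1.0836e3

    def test_reverse_scaling_divides(self):
        got = scale_conformational_rate(860.0, 0.0601, 0, "reverse", a=0.5)
        assert got == pytest.approx(860.0 / 0.0601**2, rel=1e-12)  # ~2.381e5

    def test_zero_transition_parameter_leaves_anchor(self):
        for i in range(5):
            assert scale_conformational_rate(500.0, 0.1, i, "forward", a=0.0) == 500.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            scale_conformational_rate(1.0, 0.1, 5, "forward")
        with pytest.raises(ValueError):
            scale_conformational_rate(1.0, 0.1, 2, "sideways")


class TestSchemeConstruction:
    def test_structural_counts(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        assert scheme.n_states == 20
        kinds = [r[3] for r in scheme.reactions]
        assert kinds.count("bind") == 16 and kinds.count("unbind") == 16
        assert kinds.count("flip_fwd") == 15 and kinds.count("flip_rev") == 15

    def test_rate_matrix_rows_sum_to_zero(self, glua3):
        Q = build_scheme(glua3, 1e-4, GLUA3_GLUK2_ANCHORS).rate_matrix()
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-9)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)

    def test_missing_anchor_and_bad_mode_rejected(self, glua3):
        with pytest.raises(ValueError):
            build_scheme(glua3, 1e-3, {"BS": (3e5, 860.0)})
        with pytest.raises(ValueError):
            build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS, mode="verbatim")

    def test_non_binding_conformation_rejected(self, native):
        with pytest.raises(ValueError):
            build_scheme(native, 1e-3, GLUA3_GLUK2_ANCHORS)

    @pytest.mark.parametrize("mode", ["paper_table", "thermo_consistent"])
    def test_binding_flip_cycle_consistency(self, glua3, mode):
        # equilibrium constant of each flip at i+1 ligands over that at i
        # equals 1/c (a = 0.5), matching the affinity ratio K ratios
        scheme = build_scheme(glua3, 1e-4, GLUA3_GLUK2_ANCHORS, mode=mode)
        Q = scheme.rate_matrix()
        from ampar_mwc.core import c_ratios

        ratios = c_ratios(glua3).ratios
        names = glua3.state_names
        for lo, hi in zip(names[:-1], names[1:]):
            c = ratios[f"{lo}{hi}"]
            for i in range(4):
                e_i = (Q[scheme.state_index(lo, i), scheme.state_index(hi, i)]
                       / Q[scheme.state_index(hi, i), scheme.state_index(lo, i)])
                e_next = (Q[scheme.state_index(lo, i + 1), scheme.state_index(hi, i + 1)]
                          / Q[scheme.state_index(hi, i + 1), scheme.state_index(lo, i + 1)])
                assert e_next / e_i == pytest.approx(1.0 / c, rel=1e-10)

    def test_thermo_consistent_zero_ligand_equilibrium(self, glua3):
        # k_rev(0)/k_fwd(0) of each flip equals the ratio of allosteric constants
        scheme = build_scheme(glua3, 0.0, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        Q = scheme.rate_matrix()
        names = glua3.state_names
        for lo, hi in zip(names[:-1], names[1:]):
            f0 = Q[scheme.state_index(lo, 0), scheme.state_index(hi, 0)]
            r0 = Q[scheme.state_index(hi, 0), scheme.state_index(lo, 0)]
            assert r0 / f0 == pytest.approx(glua3[hi].L / glua3[lo].L, rel=1e-10)

    def test_detailed_balance_thermo_consistent(self, glua3):
        # p_i q_ij == p_j q_ji for every edge, with p the exact closed-form
        # equilibrium (state fraction x binomial occupancy); holds at any G
        from ampar_mwc.core import liganded_distribution

        for G in (1e-6, 1e-4, 1e-3):
            scheme = build_scheme(glua3, G, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
            Q = scheme.rate_matrix()
            frac = state_fractions(glua3, [G]).fractions[:, 0]
            p = np.array([
                frac[glua3.state_names.index(c)] * liganded_distribution(glua3, c, G)[i]
                for c, i in scheme.states
            ])
            flux_fwd = p[:, None] * Q
            np.fill_diagonal(flux_fwd, 0.0)
            np.testing.assert_allclose(flux_fwd, flux_fwd.T, rtol=1e-9, atol=1e-290)


class TestSteadyState:
    def test_matches_closed_form_for_thermo_consistent(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        p = steady_state(scheme)
        marg = scheme.conformation_indicator() @ p
        closed = state_fractions(glua3, [1e-3]).fractions[:, 0]
        np.testing.assert_allclose(marg, closed, atol=1e-8)

    def test_occupancy_within_conformation_is_binomial(self, glua3):
        from ampar_mwc.core import liganded_distribution

        scheme = build_scheme(glua3, 1e-5, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        p = steady_state(scheme)
        idx = [scheme.state_index("M", i) for i in range(5)]
        cond = p[idx] / p[idx].sum()
        np.testing.assert_allclose(
            cond, liganded_distribution(glua3, "M", 1e-5), atol=1e-8
        )

    def test_reducible_chain_reported(self, glua3):
        # at G = 0 the liganded states cannot be re-entered
        scheme = build_scheme(glua3, 0.0, GLUA3_GLUK2_ANCHORS)
        with pytest.raises(ValueError, match="strongly connected"):
            steady_state(scheme)


class TestODE:
    def test_single_time_point_returns_initial(self, glua3):
        scheme = build_scheme(glua3, 1e-4, GLUA3_GLUK2_ANCHORS)
        trace = ode_timecourse(scheme, ("B", 0), [0.0])
        assert trace.occupancy[scheme.state_index("B", 0), 0] == 1.0

    def test_probability_conserved(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        trace = ode_timecourse(scheme, ("B", 0), np.linspace(0, 2e-3, 100))
        np.testing.assert_allclose(trace.occupancy.sum(axis=0), 1.0, atol=1e-8)

    def test_zero_ligand_relaxes_to_boltzmann(self, glua3):
        # thermo-consistent flips at G=0: occupancy of conformation X -> 1/L_X
        scheme = build_scheme(glua3, 0.0, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        trace = ode_timecourse(scheme, ("B", 0), np.linspace(0, 0.5, 50))
        invL = np.array([1.0 / c.L for c in glua3.conformations])
        np.testing.assert_allclose(
            trace.conformation_occupancy()[:, -1], invL / invL.sum(), atol=1e-6
        )

    def test_large_state_stabilized_within_a_millisecond(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        trace = ode_timecourse(scheme, ("B", 0), np.linspace(0, 5e-3, 2000))
        t95 = time_to_fraction_of_steady_state(trace, "L", 0.95)
        assert t95 is not None and t95 < 1e-3

    def test_bad_grid_rejected(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        with pytest.raises(ValueError):
            ode_timecourse(scheme, ("B", 0), [0.0, 0.0, 1e-3])


class TestSSA:
    def test_reproducible_given_seed(self, glua3):
        scheme = build_scheme(glua3, 1e-4, GLUA3_GLUK2_ANCHORS)
        t1 = ssa_timecourse(scheme, 20, ("B", 0), 1e-3, seed=42)
        t2 = ssa_timecourse(scheme, 20, ("B", 0), 1e-3, seed=42)
        np.testing.assert_array_equal(t1.occupancy, t2.occupancy)
        t3 = ssa_timecourse(scheme, 20, ("B", 0), 1e-3, seed=43)
        assert np.any(t1.occupancy != t3.occupancy)

    def test_counts_conserved(self, glua3):
        scheme = build_scheme(glua3, 1e-4, GLUA3_GLUK2_ANCHORS)
        trace = ssa_timecourse(scheme, 37, ("B", 0), 1e-3, seed=1)
        np.testing.assert_array_equal(trace.occupancy.sum(axis=0), 37)

    def test_single_channel_reaches_fully_liganded_large_state(self, glua3):
        # a lone receptor started unliganded-basal at high agonist walks to (L,4)
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        trace = ssa_timecourse(scheme, 1, ("B", 0), 5e-3, seed=11)
        assert trace.paths is not None
        _, states = trace.paths[0]
        assert scheme.state_index("L", 4) in states

    def test_population_mean_matches_master_equation(self, glua3):
        scheme = build_scheme(glua3, 1e-5, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        n = 400
        trace = ssa_timecourse(scheme, n, ("B", 0), 2e-3, seed=7, n_points=50)
        ode = ode_timecourse(scheme, ("B", 0), trace.times)
        p = ode.conformation_occupancy()[:, -1]
        obs = trace.conformation_occupancy()[:, -1] / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(obs - p) <= 3.5 * se + 1e-9)

    def test_time_average_matches_equilibrium(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        occ = ssa_occupancy_average(scheme, 500, ("B", 0), t_max=4e-3, seed=3, burn_in=2e-3)
        marg = scheme.conformation_indicator() @ occ
        closed = state_fractions(glua3, [1e-3]).fractions[:, 0]
        se = np.sqrt(closed * (1 - closed) / 500)
        assert np.all(np.abs(marg - closed) <= 3 * se + 1e-6)

    def test_zero_propensity_holds_state(self, glua3):
        import dataclasses

        frozen = dataclasses.replace(
            build_scheme(glua3, 0.0, GLUA3_GLUK2_ANCHORS), reactions=()
        )
        trace = ssa_timecourse(frozen, 5, ("M", 2), 1e-3, seed=2)
        assert np.all(trace.state_row("M2") == 5)


class TestSummaries:
    def test_single_exponential_rise_time(self):
        tau = 2.3e-4
        t = np.linspace(0, 20 * tau, 5000)
        y = 1 - np.exp(-t / tau)
        assert rise_time_20_80(t, y) == pytest.approx(tau * math.log(4), rel=1e-3)

    def test_step_trace_rises_instantly(self):
        t = np.linspace(0, 1.0, 1001)
        y = np.where(t < 0.5, 0.0, 1.0)
        # resolution-limited: rise time below one sample interval
        assert rise_time_20_80(t, y) <= 1e-3

    def test_plateau_free_trace_rejected(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            rise_time_20_80(t, t**3)  # still rising steeply at the end

    def test_ode_conductance_rise_under_a_millisecond(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        trace = ode_timecourse(scheme, ("B", 0), np.linspace(0, 5e-3, 2000))
        rt = rise_time_20_80(trace.times, trace.conformation_row("L"))
        assert 0 < rt < 1e-3

    def test_trace_starting_at_steady_state_needs_no_time(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        p = steady_state(scheme)
        trace = ode_timecourse(scheme, p, np.linspace(0, 1e-3, 50))
        assert time_to_fraction_of_steady_state(trace, "L", 0.95) == 0.0

    def test_not_reached_reported_as_none(self, glua3):
        scheme = build_scheme(glua3, 1e-6, GLUA3_GLUK2_ANCHORS, mode="thermo_consistent")
        trace = ode_timecourse(scheme, ("B", 0), np.linspace(0, 1e-5, 20))
        assert time_to_fraction_of_steady_state(trace, "L", 0.95) is None
        assert time_to_occupancy(trace, "L", 0.5) is None

    def test_crossing_is_interpolated(self, glua3):
        scheme = build_scheme(glua3, 1e-3, GLUA3_GLUK2_ANCHORS)
        trace = ode_timecourse(scheme, ("B", 0), np.linspace(0, 5e-3, 500))
        t95 = time_to_fraction_of_steady_state(trace, "L", 0.95)
        assert t95 not in trace.times  # falls between samples
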