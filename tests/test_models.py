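import numpy as np
import pytest
from scipy.integrate import solve_ivp

import mrcosim as m
from mrcosim.models import (
    FLUX_PER_NA,
    TC_FAST,
    TC_SLOW,
    BiochemicalModel,
    ElectricalModel,
    ElectricalParams,
    ModelConfigError,
    PulseProtocol,
    build_testcase,
    detect_spikes,
    make_synthetic_problem,
)

U_REST = {"biochemical": np.array([1.0])}


@pytest.fixture(scope="module")
def electrical():
    return ElectricalModel()


@pytest.fixture(scope="module")
def resting(electrical):
    return electrical.resting_state()


class TestElectricalModel:
    def test_resting_state_is_stationary(self, electrical, resting):
        dx = electrical.rhs(0.0, resting, U_REST)
        # derivative norm far below the resting scale (mV/s, 1/s)
        assert np.max(np.abs(dx)) < 1e-6 * 100.0

    def test_depolarizing_current_raises_soma_potential(self, electrical, resting):
        em = ElectricalModel(protocol=lambda t: 0.5)
        dx = em.rhs(0.0, resting, U_REST)
        assert dx[em.i_v_soma] > 0.0

    def test_more_active_k_channels_hyperpolarize_spine(self, electrical, resting):
        x = resting.copy()
        x[electrical.i_v_spine] = -40.0  # above rest
        d1 = electrical.rhs(0.0, x, {"biochemical": np.array([0.5])})
        d2 = electrical.rhs(0.0, x, {"biochemical": np.array([1.0])})
        assert d2[electrical.i_v_spine] < d1[electrical.i_v_spine]

    def test_gating_variables_stay_in_unit_interval(self, resting):
        em = ElectricalModel(protocol=lambda t: 0.15)
        tt = np.linspace(0.0, 0.1, 2001)
        sol = solve_ivp(
            lambda t, x: em.rhs(t, x, U_REST), (0.0, 0.1), resting,
            method="LSODA", rtol=1e-7, atol=1e-9, t_eval=tt, max_step=5e-4,
        )
        gates = sol.y[1:5]
        assert gates.min() >= -1e-6 and gates.max() <= 1.0 + 1e-6
        assert sol.y[em.i_ca].min() >= 0.0

    def test_tc_fast_variant_moves_calcium_to_biochemical_side(self):
        slow = ElectricalModel(variant=TC_SLOW)
        fast = ElectricalModel(variant=TC_FAST)
        assert slow.dim == fast.dim + 1
        assert fast.i_ca is None

    def test_output_units_flux_vs_concentration(self, resting):
        slow = ElectricalModel(variant=TC_SLOW)
        assert slow.output(resting)[0] == pytest.approx(resting[slow.i_ca])
        fast = ElectricalModel(variant=TC_FAST)
        xf = resting[: fast.dim]
        assert fast.output(xf)[0] == pytest.approx(
            -fast.i_ca_spine(xf) * FLUX_PER_NA
        )

    def test_unknown_variant_rejected(self):
        with pytest.raises(ModelConfigError):
            ElectricalModel(variant="TC-medium")


class TestBiochemicalModel:
    def test_conserved_moiety_derivatives_sum_to_zero(self):
        bm = BiochemicalModel()
        x = np.array([0.3, 0.7, 0.2, 0.8, 0.45, 0.55])
        dx = bm.rhs(0.0, x, {"electrical": np.array([0.5])})
        assert dx[0] + dx[1] == 0.0
        assert dx[2] + dx[3] == 0.0
        assert dx[4] + dx[5] == 0.0

    def test_negative_concentration_rejected(self):
        bm = BiochemicalModel()
        x = bm.initial_state()
        x[0] = -1e-3
        with pytest.raises(ModelConfigError, match="negative"):
            bm.rhs(0.0, x, None)

    def test_zero_species_derivatives_finite(self):
        bm = BiochemicalModel()
        x = np.zeros(6)
        x[bm.i_a] = bm.p.a_total
        x[bm.i_m] = bm.p.m_total
        x[bm.i_ka] = bm.p.k_total
        dx = bm.rhs(0.0, x, {"electrical": np.array([0.08])})
        assert np.all(np.isfinite(dx))

    def test_bistable_fixed_points_under_calcium_clamp(self):
        bm = BiochemicalModel()
        x0 = bm.initial_state()

        def clamp(ca, x, T=400.0):
            u = {"electrical": np.array([ca])}
            sol = solve_ivp(
                lambda t, xx: bm.rhs(t, xx, u), (0.0, T), x,
                method="LSODA", rtol=1e-9, atol=1e-12,
            )
            return sol.y[:, -1]

        low = clamp(bm.p.ca_rest, x0)
        high = clamp(1.0, x0)
        assert low[bm.i_mp] < 0.05 * bm.p.m_total
        assert high[bm.i_mp] > 0.5 * bm.p.m_total
        # true bistability: the switched state persists at basal calcium
        back = clamp(bm.p.ca_rest, high)
        assert back[bm.i_mp] > 0.5 * bm.p.m_total

    def test_flux_conversion_matches_electrical_pool(self):
        ep = ElectricalParams()
        bm = BiochemicalModel(variant=TC_FAST, elec_params=ep)
        # a given Ca current must raise both pools at the same rate
        assert bm.p.ca_per_molecule_rate * FLUX_PER_NA == pytest.approx(ep.ca_per_na)


class TestPulseProtocol:
    def test_piecewise_values(self):
        p = PulseProtocol()
        assert p(0.0) == p.baseline
        assert p(p.pulse_onset + p.pulse_width / 2) == p.pulse_amplitude
        assert p(p.pulse_onset + p.pulse_width + 1e-6) == p.baseline
        assert p(p.burst_start + 0.1) == p.burst_amplitude
        assert p(p.t_total + 1.0) == p.baseline

    def test_deterministic(self):
        p = PulseProtocol()
        ts = np.linspace(0, 5, 1001)
        a = [p(t) for t in ts]
        b = [p(t) for t in ts]
        assert a == b

    def test_spike_detection_interpolates_crossings(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([-10.0, 10.0, -10.0, 10.0])
        sp = detect_spikes(t, v)
        np.testing.assert_allclose(sp, [0.5, 2.5])


class TestSignalSmoothness:
    def test_concentration_far_smoother_than_flux(self, resting):
        """The exchanged concentration signal (TC-slow) is an order of
        magnitude smoother than the flux signal (TC-fast) over a burst
        episode, by max-slope and total-variation relative to range."""
        em = ElectricalModel(protocol=PulseProtocol())
        tt = np.linspace(4.0, 4.4, 80001)
        sol = solve_ivp(
            lambda t, x: em.rhs(t, x, U_REST), (4.0, 4.4), resting,
            method="LSODA", rtol=1e-8, atol=1e-10, t_eval=tt, max_step=5e-4,
        )
        flux = np.array([-em.i_ca_spine(sol.y[:, i]) for i in range(len(tt))])
        ca = sol.y[em.i_ca]

        def maxslope(sig):
            return np.max(np.abs(np.gradient(sig, tt))) / np.ptp(sig)

        def total_variation(sig):
            return np.sum(np.abs(np.diff(sig))) / np.ptp(sig)

        assert maxslope(flux) / maxslope(ca) > 10.0
        assert total_variation(flux) / total_variation(ca) > 10.0


class TestCoupledTestCase:
    @pytest.mark.parametrize("variant", [TC_SLOW, TC_FAST])
    def test_monolithic_rhs_consistent_with_components(self, variant):
        tc = build_testcase(variant)
        x = tc.x0_monolithic()
        dx = tc.monolithic_rhs(0.0, x)
        xe, xb = x[: tc.n_elec], x[tc.n_elec :]
        u_e = {"biochemical": tc.biochemical.output(xb)}
        u_b = {"electrical": tc.electrical.output(xe)}
        np.testing.assert_array_equal(dx[: tc.n_elec], tc.electrical.rhs(0.0, xe, u_e))
        np.testing.assert_array_equal(dx[tc.n_elec :], tc.biochemical.rhs(0.0, xb, u_b))

    def test_observable_indices_resolve(self):
        tc = build_testcase(TC_SLOW)
        for name in ("V", "Ca", "K_A", "P_MAPK"):
            idx = tc.observable_monolithic_index(name)
            assert 0 <= idx < tc.n_elec + tc.n_bioch

    def test_short_coupled_run_tracks_monolithic_reference(self):
        proto = PulseProtocol(t_total=0.2, burst_start=0.15, pulse_onset=0.05)
        tc = build_testcase(TC_SLOW, protocol=proto)
        res = m.MultirateEngine(
            tc.components(rel_tol=1e-4), m.EngineConfig(t_end=0.15)
        ).run()
        assert res.status == "completed"
        ref = m.compute_reference(tc, 0.15, tol=1e-10)
        xT = ref(0.15)
        for name in ("V", "Ca", "K_A"):
            cid, idx = tc.observables[name]
            val = res.state_at(cid, 0.15)[idx]
            rv = xT[tc.observable_monolithic_index(name)]
            assert val == pytest.approx(rv, rel=5e-2, abs=1e-8)


class TestSyntheticProblem:
    def test_closed_form_matches_monolithic_solve(self, synthetic_smooth):
        ref = m.compute_reference(synthetic_smooth, 1.0, tol=1e-12)
        t_check = np.linspace(0.1, 1.0, 7)
        exact = synthetic_smooth.reference(t_check)
        solved = np.vstack([ref(t) for t in t_check])
        np.testing.assert_allclose(solved, exact, rtol=1e-7, atol=1e-9)

    def test_zero_coupling_slow_is_pure_exponential(self):
        prob = make_synthetic_problem(coupling_strength=0.0, pulse_amplitude=0.0)
        t = np.array([0.0, 0.5, 1.5])
        x1 = prob.reference(t)[:, 0]
        np.testing.assert_allclose(x1, prob.x0[0] * np.exp(-t / prob.tau_slow), rtol=1e-12)

    def test_stiffness_ratio_configures_time_constants(self):
        prob = make_synthetic_problem(stiffness_ratio=250.0)
        assert prob.tau_slow / prob.tau_fast == pytest.approx(250.0)
        with pytest.raises(ModelConfigError):
            make_synthetic_problem(stiffness_ratio=0.5)

    def test_signal_speed_selects_exchanged_state(self):
        fast = make_synthetic_problem(signal_speed="fast")
        slow = make_synthetic_problem(signal_speed="slow")
        x = np.array([3.0, 7.0])
        assert fast.g_fast(x)[0] == 3.0
        assert slow.g_fast(x)[0] == 7.0

    def test_filtered_signal_is_smoother(self):
        prob = make_synthetic_problem(pulse_amplitude=0.0)
        ref = prob.reference(np.linspace(0.2, 1.0, 4001))
        y, z = ref[:, 1], ref[:, 2]
        assert np.sum(np.abs(np.diff(z))) / np.ptp(z) < np.sum(np.abs(np.diff(y))) / np.ptp(y)

    def test_reference_self_consistency_two_tolerances(self):
        prob = make_synthetic_problem()  # with pulses: no closed form
        r12 = m.compute_reference(prob, 0.2, tol=1e-12)
        r10 = m.compute_reference(prob, 0.2, tol=1e-10)
        a, b = r12(0.2), r10(0.2)
        assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-12)) < 1e-7

    def test_closed_form_refused_with_pulses(self):
        prob = make_synthetic_problem()
        with pytest.raises(ModelConfigError, match="closed form"):
            prob.reference(0.5)


def test_protocol_sustains_target_firing_regimes(resting):
    """Regular phase fires one spike per 2 Hz pulse; burst phase ~100 Hz
    (independent stiff solver as oracle; short windows for speed)."""
    proto = PulseProtocol()
    em = ElectricalModel(protocol=proto)
    tt1 = np.linspace(0.0, 1.0, 20001)
    sol1 = solve_ivp(lambda t, x: em.rhs(t, x, U_REST), (0.0, 1.0), resting,
                     method="LSODA", rtol=1e-7, atol=1e-9, t_eval=tt1, max_step=1e-3)
    sp1 = detect_spikes(tt1, sol1.y[0])
    assert len(sp1) == 2  # 2 pulses in the first second, one spike each

    tt2 = np.linspace(4.0, 4.5, 20001)
    sol2 = solve_ivp(lambda t, x: em.rhs(t, x, U_REST), (4.0, 4.5), resting,
                     method="LSODA", rtol=1e-7, atol=1e-9, t_eval=tt2, max_step=1e-3)
    rate = len(detect_spikes(tt2, sol2.y[0])) / 0.5
    assert 85.0 <= rate <= 115.0

    # regular spiking is regular: inter-spike CV under sustained near-rheobase
    # current stays small
    em3 = ElectricalModel(protocol=lambda t: 0.08)
    tt3 = np.linspace(0.0, 2.0, 40001)
    sol3 = solve_ivp(lambda t, x: em3.rhs(t, x, U_REST), (0.0, 2.0), resting,
                     method="LSODA", rtol=1e-7, atol=1e-9, t_eval=tt3, max_step=1e-3)
    sp3 = detect_spikes(tt3, sol3.y[0])
    isi = np.diff(sp3[sp3 > 1.0])  # discard the adaptation transient
    assert len(isi) >= 3
    assert np.std(isi) / np.mean(isi) < 0.1
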