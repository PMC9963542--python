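"""Scenario assembly: channel-flow benchmark behaviour, steady-state
detection, sweeps, fixtures and the focusing run contracts."""

import dataclasses

import numpy as np
import pytest

from acoustolbm.exceptions import ConfigurationError, WallContactError
from acoustolbm.scenarios import (ChannelConfig, FocusingSetup, Trajectory,
                                  detect_steady_state, load_cavity_reference,
                                  load_drag_reference,
                                  reference_drag_coefficient, run_cavity,
                                  run_focusing, run_poiseuille, sweep)


@pytest.fixture(scope="module")
def poiseuille_result():
    # the flow is x-invariant, so a 4-node axial extent suffices
    return run_poiseuille(grid=(4, 40), tol=1e-8)


class TestPoiseuille:
    @pytest.fixture()
    def result(self, poiseuille_result):
        return poiseuille_result

    def test_profile_matches_analytic_parabola(self, result):
        assert result.error_norm < 0.01

    def test_maximum_at_centreline_zero_at_walls(self, result):
        u = result.samples.u_sim.to_numpy()
        assert np.argmax(u) in (19, 20)
        assert u[0] < 0.06 * u.max()
        assert u[-1] < 0.06 * u.max()

    def test_profile_symmetric(self, result):
        u = result.samples.u_sim.to_numpy()
        np.testing.assert_allclose(u, u[::-1], atol=1e-10 * u.max())

    def test_axially_invariant(self, result):
        state = result.meta["state"]
        np.testing.assert_allclose(state.u[0] - state.u[0][0][np.newaxis, :],
                                   0.0, atol=1e-10)

    def test_grid_refinement_reduces_error(self, result):
        fine = run_poiseuille(grid=(4, 80), tol=1e-8, max_steps=150000)
        assert fine.error_norm < result.error_norm


class TestCavityEdgeCases:
    def test_zero_lid_speed_stays_quiescent(self):
        result = run_cavity(lid_speed=0.0)
        state = result.meta["state"]
        np.testing.assert_allclose(state.u, 0.0, atol=1e-14)
        assert result.error_norm == 0.0

    def test_lid_speed_above_mach_limit_rejected(self):
        with pytest.raises(ConfigurationError):
            run_cavity(lid_speed=0.4)


class TestFixtures:
    def test_cavity_reference_profile(self):
        ref = load_cavity_reference()
        assert len(ref) == 17
        assert ref.y.iloc[0] == 0.0 and ref.y.iloc[-1] == 1.0
        assert ref.u.iloc[-1] == 1.0  # lid value

    def test_drag_reference_monotone_decreasing(self):
        tab = load_drag_reference()
        assert (np.diff(tab.cd) < 0).all()
        assert reference_drag_coefficient(1.0) == pytest.approx(11.11, abs=0.01)

    def test_drag_reference_range_checked(self):
        with pytest.raises(ConfigurationError):
            reference_drag_coefficient(100.0)


def _synthetic_traj(times, y):
    n = len(times)
    zeros = np.zeros(n)
    return Trajectory(times=np.asarray(times), centroid_x=zeros.copy(),
                      centroid_y=np.asarray(y), centroid_velocity=zeros.copy(),
                      applied_force=zeros.copy())


class TestDetectSteadyState:
    def test_constant_series_settles_immediately(self):
        t = np.arange(100.0)
        settled, t_settle = detect_steady_state(
            _synthetic_traj(t, np.full(100, 8e-5)), tolerance=0.5e-6, window=10)
        assert settled
        assert t_settle == 0.0

    def test_exponential_approach_crossing_time(self):
        # y(t) = node + A exp(-t/tau): the window criterion starts holding
        # within one window of the analytic tolerance crossing
        tau_s, amp, tol, w = 400.0, 1e-5, 0.5e-6, 50
        t = np.arange(4000.0)
        y = 80e-6 + amp * np.exp(-t / tau_s)
        settled, t_settle = detect_steady_state(_synthetic_traj(t, y),
                                                tolerance=tol, window=w)
        assert settled
        # analytic onset of the window criterion: for a monotone convex decay
        # the worst deviation from the window median is the leading half-span,
        # A exp(-t0/tau) (1 - exp(-W/(2 tau))) = tol
        t_cross = tau_s * np.log(amp * (1 - np.exp(-w / (2 * tau_s))) / tol)
        assert abs(t_settle - t_cross) < w

    def test_drifting_series_never_settles(self):
        t = np.arange(500.0)
        y = 70e-6 + 5e-8 * t  # 50 nm/sample drift
        settled, _ = detect_steady_state(_synthetic_traj(t, y),
                                         tolerance=0.5e-6, window=50)
        assert not settled

    def test_window_shorter_than_series_required(self):
        t = np.arange(5.0)
        settled, t_settle = detect_steady_state(
            _synthetic_traj(t, np.full(5, 1e-5)), tolerance=1e-6, window=50)
        assert not settled and t_settle is None


class TestFocusingContracts:
    def test_without_acoustics_particle_keeps_its_lane(self):
        s = FocusingSetup.default(initial_y=70e-6)
        acoustic = dataclasses.replace(s.acoustic, active=False)
        traj = run_focusing(s.particle, acoustic, s.channel, 70e-6,
                            max_steps=20000)
        assert not traj.settled  # never settles *at a node*
        drift = abs(traj.centroid_y[-1] - traj.centroid_y[0])
        assert drift < 2e-6  # under one lattice cell
        # it advects downstream meanwhile
        assert traj.centroid_x[-1] > traj.centroid_x[0]

    def test_advects_at_local_flow_speed(self):
        # at the centreline the particle should ride the Poiseuille maximum
        s = FocusingSetup.default(initial_y=80e-6)
        acoustic = dataclasses.replace(s.acoustic, active=False)
        traj = run_focusing(s.particle, acoustic, s.channel, 80e-6,
                            max_steps=6000, stop_when_settled=False)
        vx = (traj.centroid_x[-1] - traj.centroid_x[0]) / (
            traj.times[-1] - traj.times[0])
        u_center = 0.70 * 1e-6 / 160e-6  # Re nu / H
        assert vx == pytest.approx(u_center, rel=0.05)

    def test_initial_position_outside_channel_rejected(self):
        s = FocusingSetup.default()
        with pytest.raises(ConfigurationError):
            run_focusing(s.particle, s.acoustic, s.channel, 170e-6)

    def test_strong_sedimentation_hits_wall(self):
        s = FocusingSetup.default(initial_y=40e-6)
        acoustic = dataclasses.replace(s.acoustic, active=False)
        with pytest.raises(WallContactError) as err:
            run_focusing(s.particle, acoustic, s.channel, 40e-6,
                         max_steps=120000, gravity=-2e-8)
        assert err.value.trajectory is not None
        assert len(err.value.trajectory.centroid_y) > 1

    def test_trajectory_invariants(self):
        s = FocusingSetup.default(initial_y=76e-6)
        traj = run_focusing(s.particle, s.acoustic, s.channel, 76e-6)
        assert (np.diff(traj.times) > 0).all()
        assert traj.settled
        assert traj.node_positions_m == pytest.approx([80e-6])
        assert abs(traj.steady_y - 80e-6) < s.steady_tolerance


class TestSweep:
    def test_single_value_sweep_equals_direct_run(self):
        base = FocusingSetup.default(initial_y=75e-6, max_steps=40000)
        out = sweep("initial_y", [75e-6], base)
        direct = run_focusing(base.particle, base.acoustic, base.channel,
                              75e-6, max_steps=40000)
        traj = out[75e-6]
        np.testing.assert_array_equal(traj.centroid_y, direct.centroid_y)
        assert traj.settle_time == direct.settle_time

    def test_unsupported_parameter(self):
        with pytest.raises(ConfigurationError):
            sweep("color", [1], FocusingSetup.default())

    def test_empty_values(self):
        with pytest.raises(ConfigurationError):
            sweep("radius", [], FocusingSetup.default())

    def test_member_error_carries_its_key(self):
        base = FocusingSetup.default()
        with pytest.raises(ConfigurationError, match="initial_y=1e-09"):
            sweep("initial_y", [1e-9], base)


class TestLinearizedDynamicsRecovery:
    def test_recovers_configured_force_slope(self):
        """Fit the near-node relaxation rate and an independently measured
        mobility; together they recover the configured E_ac * Phi force slope
        within 10%."""
        s = FocusingSetup.default(initial_y=80e-6)
        # mobility run: constant known lateral force (gravity knob), no sound
        g_force = -3e-10  # N
        acoustic_off = dataclasses.replace(s.acoustic, active=False)
        traj_g = run_focusing(s.particle, acoustic_off, s.channel, 80e-6,
                              max_steps=12000, gravity=g_force,
                              stop_when_settled=False)
        tail = slice(len(traj_g.times) // 2, None)
        v_term = np.polyfit(traj_g.times[tail], traj_g.centroid_y[tail], 1)[0]
        mobility = v_term / g_force  # (m/s)/N
        # focusing run: fit exponential approach to the node
        traj = run_focusing(s.particle, s.acoustic, s.channel, 74e-6)
        d = traj.centroid_y - 80e-6
        mask = (np.abs(d) > 0.5e-6) & (np.abs(d) < 4e-6)
        rate = -np.polyfit(traj.times[mask], np.log(np.abs(d[mask])), 1)[0]
        # near the node F = -k_slope (y - y_node), k_slope = 8 pi^2 Vp Eac Phi / lambda^2
        k_fit = rate / mobility
        lam = s.acoustic.wavelength
        from acoustolbm.acoustics import contrast_factor
        phi = contrast_factor(s.particle.compressibility,
                              s.acoustic.fluid_compressibility,
                              s.particle.density, s.acoustic.fluid_density)
        k_cfg = 8 * np.pi**2 * s.particle.volume * s.acoustic.eac * phi / lam**2
        assert k_fit == pytest.approx(k_cfg, rel=0.10)
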