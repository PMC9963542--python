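"""Lagrangian membrane and fluid coupling: discretization, hat kernel,
spreading/interpolation, constitutive forces, rigidification, advection and
drag normalization."""

import numpy as np
import pytest

from acoustolbm.exceptions import (ConfigurationError, InvalidParameterError,
                                   OutOfDomainError)
from acoustolbm.immersed_boundary import (NoSlipObstacle, ParticleSpec,
                                          advance_membrane,
                                          constitutive_forces, delta_weight,
                                          drag_coefficient,
                                          interpolate_velocity,
                                          make_circle_membrane,
                                          membrane_fluid_velocity,
                                          particle_from_library,
                                          rigid_particle_forces,
                                          spread_forces)
from acoustolbm.lbm_core import LatticeState, equilibrium, step


class TestParticleSpec:
    def test_volume_is_sphere(self):
        p = ParticleSpec(radius=5e-6, density=1050.0, compressibility=2.49e-10)
        assert p.volume == pytest.approx(4 / 3 * np.pi * (5e-6) ** 3, rel=1e-12)

    def test_library_lookup(self):
        p = particle_from_library("iron_oxide", 3e-6)
        assert p.density == 1500.0
        assert p.compressibility == 1.5e-11
        with pytest.raises(ConfigurationError):
            particle_from_library("granite", 3e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            ParticleSpec(radius=0.0, density=1.0, compressibility=1.0)


class TestMakeCircleMembrane:
    def test_centroid_and_radii(self):
        m = make_circle_membrane((10.0, 12.5), 2.5)
        np.testing.assert_allclose(m.centroid, [10.0, 12.5])
        radii = np.hypot(*(m.nodes - m.centroid).T)
        np.testing.assert_allclose(radii, 2.5, atol=1e-12)

    def test_ten_micron_particle_on_table1_lattice(self, table1_units):
        radius_lat = 5e-6 / table1_units.cf_length  # 10 um diameter particle
        assert radius_lat == pytest.approx(2.5, rel=1e-12)
        m = make_circle_membrane((10.0, 10.0), radius_lat, 0.65)
        assert m.n_nodes == int(np.ceil(2 * np.pi * 2.5 / 0.65))

    def test_node_spacing_in_bounds(self):
        m = make_circle_membrane((0.0, 0.0), 4.0, 0.65)
        spacing = 2 * np.pi * 4.0 / m.n_nodes
        assert 0.3 < spacing <= 1.0

    def test_bad_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            make_circle_membrane((0, 0), 2.0, 1.5)

    def test_too_small_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_circle_membrane((0, 0), -1.0, 0.65)


class TestDeltaWeight:
    def test_on_site(self):
        assert delta_weight(0.0, 0.0) == 1.0

    @pytest.mark.parametrize("dx", [1.0, -1.0, 1.5])
    def test_outside_support(self, dx):
        assert delta_weight(dx, 0.3) == 0.0

    def test_cell_center(self):
        assert delta_weight(0.5, 0.5) == pytest.approx(0.25)

    def test_partition_of_unity(self, rng):
        # the four surrounding sites always share the full weight
        for _ in range(50):
            fx, fy = rng.random(2)
            total = (delta_weight(fx, fy) + delta_weight(1 - fx, fy)
                     + delta_weight(fx, 1 - fy) + delta_weight(1 - fx, 1 - fy))
            assert total == pytest.approx(1.0, abs=1e-12)


class TestSpreadForces:
    def test_node_on_lattice_site(self):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        m.nodes = np.array([[4.0, 5.0]])
        m.forces = np.array([[1.5, -2.0]])
        field = np.zeros((2, 16, 16))
        spread_forces(m, field)
        assert field[0, 4, 5] == 1.5
        assert field[1, 4, 5] == -2.0
        assert np.abs(field).sum() == pytest.approx(3.5)

    def test_cell_center_splits_into_quarters(self):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        m.nodes = np.array([[4.5, 5.5]])
        m.forces = np.array([[1.0, 0.0]])
        field = np.zeros((2, 16, 16))
        spread_forces(m, field)
        for i, j in ((4, 5), (5, 5), (4, 6), (5, 6)):
            assert field[0, i, j] == pytest.approx(0.25)

    def test_total_force_conserved(self, rng):
        m = make_circle_membrane((8.3, 7.9), 3.2)
        m.forces = rng.normal(size=m.nodes.shape)
        field = np.zeros((2, 16, 16))
        spread_forces(m, field)
        np.testing.assert_allclose(field.sum(axis=(1, 2)),
                                   m.forces.sum(axis=0), atol=1e-12)

    def test_out_of_domain_raises(self):
        m = make_circle_membrane((2.0, 1.0), 1.5)
        m.forces[:] = 1.0
        with pytest.raises(OutOfDomainError):
            spread_forces(m, np.zeros((2, 16, 16)))


class TestInterpolateVelocity:
    def test_uniform_field(self):
        m = make_circle_membrane((8.1, 7.7), 3.0)
        u = np.zeros((2, 16, 16))
        u[0], u[1] = 0.3, -0.1
        v = interpolate_velocity(u, m)
        np.testing.assert_allclose(v[:, 0], 0.3, atol=1e-14)
        np.testing.assert_allclose(v[:, 1], -0.1, atol=1e-14)

    def test_linear_field_reproduced_exactly(self, rng):
        a, bx, by = rng.normal(size=3)
        x = np.arange(20)[:, None] * np.ones(18)
        y = np.ones((20, 1)) * np.arange(18)
        u = np.stack([a + bx * x + by * y, np.zeros_like(x)])
        m = make_circle_membrane((9.37, 8.21), 3.3)
        v = interpolate_velocity(u, m)
        expected = a + bx * m.nodes[:, 0] + by * m.nodes[:, 1]
        np.testing.assert_allclose(v[:, 0], expected, rtol=1e-12)

    def test_node_on_site_takes_site_value(self, rng):
        u = rng.random((2, 16, 16))
        m = make_circle_membrane((8.0, 8.0), 3.0)
        m.nodes = np.array([[5.0, 9.0]])
        v = interpolate_velocity(u, m)
        np.testing.assert_allclose(v[0], u[:, 5, 9], atol=1e-14)

    def test_distribution_based_interpolation_matches(self, rng):
        f = equilibrium(1.0 + 0.05 * rng.random((16, 16)),
                        0.02 * (rng.random((2, 16, 16)) - 0.5))
        state = LatticeState(f, tau=0.8)
        m = make_circle_membrane((8.2, 7.6), 3.1)
        np.testing.assert_allclose(membrane_fluid_velocity(state, m),
                                   interpolate_velocity(state.u, m),
                                   atol=1e-14)


class TestConstitutiveForces:
    def test_undeformed_gives_zero(self):
        m = make_circle_membrane((8.0, 8.0), 3.0, stiffness=0.5)
        constitutive_forces(m)
        np.testing.assert_allclose(m.forces, 0.0, atol=1e-14)

    def test_displaced_node_restoring_force(self):
        m = make_circle_membrane((8.0, 8.0), 3.0, stiffness=0.5)
        m.nodes[3] += [0.2, -0.1]
        constitutive_forces(m)
        np.testing.assert_allclose(m.forces[3], [-0.1, 0.05], atol=1e-14)

    def test_rigid_translation_is_force_free(self):
        m = make_circle_membrane((8.0, 8.0), 3.0, stiffness=0.5)
        m.nodes = m.nodes + [1.3, -0.7]
        m.centroid = m.centroid + [1.3, -0.7]
        constitutive_forces(m)
        np.testing.assert_allclose(m.forces, 0.0, atol=1e-13)

    def test_external_share_added(self):
        m = make_circle_membrane((8.0, 8.0), 3.0, stiffness=0.5)
        constitutive_forces(m, (0.0, 2e-3))
        np.testing.assert_allclose(m.forces[:, 1], 2e-3, atol=1e-15)


class TestRigidParticleForces:
    def test_net_force_equals_external(self, rng):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        v = rng.normal(size=m.nodes.shape)
        rigid_particle_forces(m, v, (1e-4, -3e-4))
        np.testing.assert_allclose(m.forces.sum(axis=0), [1e-4, -3e-4],
                                   atol=1e-15)

    def test_rigid_motion_unopposed(self):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        v = np.tile([0.01, -0.02], (m.n_nodes, 1))
        rigid_particle_forces(m, v)
        np.testing.assert_allclose(m.forces, 0.0, atol=1e-16)


class TestAdvanceMembrane:
    def test_zero_velocity_is_identity(self):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        nodes0 = m.nodes.copy()
        advance_membrane(m, np.zeros_like(m.nodes))
        np.testing.assert_array_equal(m.nodes, nodes0)

    def test_uniform_velocity_displaces_centroid(self):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        v = np.tile([0.1, 0.05], (m.n_nodes, 1))
        for _ in range(7):
            advance_membrane(m, v)
        np.testing.assert_allclose(m.centroid, [8.7, 8.35], atol=1e-12)

    def test_passive_tracer_in_uniform_flow(self):
        # zero-slip contract: the advected ring tracks the flow to within
        # one lattice cell over 1000 steps
        state = LatticeState.quiescent(24, 24, tau=0.8, u0=(1e-3, 0.0))
        m = make_circle_membrane((12.0, 12.0), 3.0)
        for _ in range(1000):
            v = membrane_fluid_velocity(state, m, periodic_x=True)
            step(state)
            advance_membrane(m, v)
        assert m.centroid[0] - 12.0 == pytest.approx(1.0, abs=0.05)
        assert abs(m.centroid[1] - 12.0) < 1e-6

    def test_bad_dt(self):
        m = make_circle_membrane((8.0, 8.0), 3.0)
        with pytest.raises(InvalidParameterError):
            advance_membrane(m, np.zeros_like(m.nodes), dt=0.0)


class TestDragCoefficient:
    def test_direct_formula(self):
        assert drag_coefficient(1.0, 1.0, 1.0, 1.0) == 2.0

    def test_quadratic_in_speed(self):
        cd1 = drag_coefficient(1.0, 1.0, 1.0, 1.0)
        cd2 = drag_coefficient(1.0, 1.0, 1.0, 2.0)
        assert cd2 == pytest.approx(cd1 / 4)

    def test_zero_speed_raises(self):
        with pytest.raises(ZeroDivisionError):
            drag_coefficient(1.0, 1.0, 1.0, 0.0)


class TestNoSlipObstacle:
    def test_action_reaction_with_fluid(self, rng):
        f = equilibrium(np.ones((20, 20)), 0.02 * rng.random((2, 20, 20)))
        state = LatticeState(f, tau=0.8)
        m = make_circle_membrane((10.0, 10.0), 3.0, mobile=False)
        obstacle = NoSlipObstacle(m, (20, 20))
        df = obstacle.enforce(state)
        np.testing.assert_allclose(state.body_force.sum(axis=(1, 2)),
                                   df.sum(axis=0), atol=1e-13)
        np.testing.assert_allclose(obstacle.reaction(), -df.sum(axis=0),
                                   atol=1e-15)

    def test_quiescent_fluid_needs_no_force(self):
        state = LatticeState.quiescent(20, 20, tau=0.8)
        m = make_circle_membrane((10.0, 10.0), 3.0, mobile=False)
        df = NoSlipObstacle(m, (20, 20)).enforce(state)
        np.testing.assert_allclose(df, 0.0, atol=1e-15)
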