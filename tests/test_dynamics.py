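"""Spring-network energetics, analytic forces, and Langevin integration."""

import numpy as np
import pytest

from actinmech import dynamics
from actinmech.dynamics import (
    KB,
    ForceProtocol,
    IntegratorParams,
    Trajectory,
    compute_forces,
    load_xyz_trajectory,
    run_dynamics,
    save_xyz_trajectory,
    total_energy,
)
from actinmech.lattice import (
    FilamentConfiguration,
    LatticeParams,
    MechanicalParams,
    SpringTopology,
    build_canonical_lattice,
    derive_topology,
)


def _single_bond_topology(l0: float) -> SpringTopology:
    return SpringTopology(
        bonds=np.array([[0, 1]]),
        bond_type=np.array(["lateral"]),
        bond_l0=np.array([l0]),
        angles=np.zeros((0, 3), int),
        angle_theta0=np.zeros(0),
        dihedrals=np.zeros((0, 4), int),
        dihedral_phi0=np.zeros(0),
        dihedral_rest_sines=np.zeros((0, 2)),
        n_subunits=2,
    )


class TestEnergy:
    def test_equilibrium_energy_is_zero(self, canonical100, mech):
        config, topo = canonical100
        assert total_energy(config, topo, mech) == 0.0

    def test_single_stretched_bond(self):
        # 1/2 * 10 pN/nm * (0.1 nm)^2 = 0.05 pN nm
        topo = _single_bond_topology(1.0)
        mech = MechanicalParams(k_l=10.0, k_theta=1e-12, k_phi=1e-12)
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.1]])
        assert total_energy(pos, topo, mech) == pytest.approx(0.05)

    def test_rigid_motion_invariance(self, perturbed40, mech):
        pos, topo = perturbed40
        e0 = total_energy(pos, topo, mech)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [0.3, -1.2, 0.8]).as_matrix()
        moved = pos @ rot.T + np.array([5.0, -3.0, 11.0])
        assert total_energy(moved, topo, mech) == pytest.approx(e0, rel=1e-9)

    def test_literal_transcription_oracle(self, perturbed40):
        """Independent per-term re-evaluation of the three potentials."""
        pos, topo = perturbed40
        mech = MechanicalParams(250.0, 120.0, 80.0, dihedral_mode="cosine")

        expected = 0.0
        for (i, j), k, l0 in zip(topo.bonds, mech.bond_k(topo.bond_type), topo.bond_l0):
            l = np.linalg.norm(pos[j] - pos[i])
            expected += 0.5 * k * (l - l0) ** 2
        for (j, i, k), t0 in zip(topo.angles, topo.angle_theta0):
            u, v = pos[j] - pos[i], pos[k] - pos[i]
            theta = np.arccos(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            )
            expected += 0.5 * mech.k_theta * (theta - t0) ** 2
        for (a, b, c, d), p0 in zip(topo.dihedrals, topo.dihedral_phi0):
            b1, b2, b3 = pos[b] - pos[a], pos[c] - pos[b], pos[d] - pos[c]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            m = np.cross(n1, b2 / np.linalg.norm(b2))
            phi = np.arctan2(np.dot(m, n2), np.dot(n1, n2))
            expected += mech.k_phi * (1.0 - np.cos(phi - p0))

        assert total_energy(pos, topo, mech) == pytest.approx(expected, rel=1e-12)

    def test_coincident_points_rejected(self, canonical40, mech):
        config, topo = canonical40
        pos = config.positions.copy()
        pos[1] = pos[0]
        with pytest.raises(ValueError):
            total_energy(pos, topo, mech)


class TestForces:
    @pytest.mark.parametrize("mode", ["cosine", "tapered"])
    def test_match_finite_differences(self, perturbed40, mode):
        pos, topo = perturbed40
        mech = MechanicalParams(300.0, 100.0, 150.0, dihedral_mode=mode)
        forces = compute_forces(pos, topo, mech)
        h = 1e-6
        for i in range(0, len(pos), 5):
            for ax in range(3):
                pp = pos.copy()
                pp[i, ax] += h
                pm = pos.copy()
                pm[i, ax] -= h
                fd = -(total_energy(pp, topo, mech) - total_energy(pm, topo, mech)) / (
                    2 * h
                )
                assert abs(fd - forces[i, ax]) < 1e-4

    @pytest.mark.parametrize("mode", ["cosine", "tapered"])
    def test_compiled_kernel_matches_reference(self, perturbed40, mode):
        pos, topo = perturbed40
        mech = MechanicalParams(300.0, 100.0, 150.0, dihedral_mode=mode)
        reference = compute_forces(pos, topo, mech)
        fast = dynamics._force_evaluator(topo, mech, use_kernels=True)(pos)
        np.testing.assert_allclose(fast, reference, atol=1e-9)

    def test_zero_at_equilibrium(self, canonical100, mech):
        config, topo = canonical100
        forces = compute_forces(config, topo, mech)
        assert np.abs(forces).max() < 1e-10

    def test_net_force_and_torque_vanish(self, perturbed40, mech):
        pos, topo = perturbed40
        forces = compute_forces(pos, topo, mech)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9
        torque = np.cross(pos, forces).sum(axis=0)
        assert np.abs(torque).max() < 1e-8

    def test_two_particle_hooke(self):
        topo = _single_bond_topology(1.0)
        mech = MechanicalParams(k_l=10.0, k_theta=1e-12, k_phi=1e-12)
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.25]])
        forces = compute_forces(pos, topo, mech)
        np.testing.assert_allclose(forces[0], [0, 0, 10.0 * 0.25], atol=1e-12)
        np.testing.assert_allclose(forces[1], -forces[0], atol=1e-12)


class TestIntegration:
    def test_zero_force_thermostat_off_stays_at_equilibrium(self, canonical40, mech):
        config, topo = canonical40
        protocol = ForceProtocol(per_particle_force=0.0, n_fixed=0, n_loaded=1)
        integ = IntegratorParams(
            dt=0.01, thermostat_on=False, friction=1.0, seed=0, n_steps=200, save_every=50
        )
        traj = run_dynamics(config, topo, mech, protocol, integ)
        np.testing.assert_allclose(traj.frames[-1], config.positions, atol=1e-12)

    def test_vacuum_energy_conservation(self, canonical40, mech):
        config, topo = canonical40
        rng = np.random.default_rng(3)
        start = FilamentConfiguration(
            config.positions + rng.normal(0, 0.02, config.positions.shape)
        )
        e0 = total_energy(start, topo, mech)
        protocol = ForceProtocol(per_particle_force=0.0, n_fixed=0, n_loaded=1)
        integ = IntegratorParams(
            dt=0.0005, thermostat_on=False, friction=1.0, seed=0,
            n_steps=10000, save_every=10000,
        )
        traj = run_dynamics(config=start, topo=topo, mech=mech, protocol=protocol, integ=integ) if False else run_dynamics(start, topo, mech, protocol, integ)
        e_final = total_energy(traj.frames[-1], topo, mech) + traj.kinetic_energy[-1]
        assert abs(e_final - e0) < 0.001 * e0

    def test_equipartition_two_particle(self):
        """Stationary velocity variance of the thermostat matches kT/m."""
        topo = _single_bond_topology(2.78)
        mech = MechanicalParams(k_l=400.0, k_theta=1e-12, k_phi=1e-12)
        config = FilamentConfiguration(np.array([[0, 0, 0], [0, 0, 2.78]]))
        protocol = ForceProtocol(per_particle_force=0.0, n_fixed=0, n_loaded=1)
        integ = IntegratorParams(
            dt=0.005, temperature=298.0, friction=0.5, seed=4,
            n_steps=200000, save_every=100,
        )
        traj = run_dynamics(config, topo, mech, protocol, integ)
        mean_ke = traj.kinetic_energy[200:].mean()
        expected = 3.0 * KB * 298.0  # 2 particles x (3/2) kT
        assert mean_ke == pytest.approx(expected, rel=0.05)

    def test_fixed_particles_do_not_move(self, canonical40, mech):
        config, topo = canonical40
        protocol = ForceProtocol(mode="constant", sense="tension")
        integ = IntegratorParams(dt=0.002, seed=1, n_steps=2000, save_every=500)
        traj = run_dynamics(config, topo, mech, protocol, integ)
        for frame in traj.frames:
            np.testing.assert_array_equal(frame[:5], config.positions[:5])

    def test_bitwise_reproducible_for_seed(self, canonical40, mech):
        config, topo = canonical40
        protocol = ForceProtocol(mode="constant", sense="compression")
        integ = IntegratorParams(dt=0.002, seed=9, n_steps=1000, save_every=250)
        t1 = run_dynamics(config, topo, mech, protocol, integ)
        t2 = run_dynamics(config, topo, mech, protocol, integ)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_divergence_raises_with_step_number(self, canonical40, mech):
        config, topo = canonical40
        protocol = ForceProtocol(mode="constant", sense="compression")
        integ = IntegratorParams(dt=0.5, seed=0, n_steps=5000, save_every=100)
        with pytest.raises(FloatingPointError, match="step"):
            run_dynamics(config, topo, mech, protocol, integ)

    def test_apply_release_requires_release_frames(self, canonical40, mech):
        config, topo = canonical40
        protocol = ForceProtocol(mode="apply_release", sense="tension")
        integ = IntegratorParams(dt=0.002, seed=0, n_steps=100)
        with pytest.raises(ValueError):
            run_dynamics(config, topo, mech, protocol, integ)


class TestTrajectoryIO:
    def test_xyz_round_trip(self, canonical40, mech, tmp_path):
        config, topo = canonical40
        protocol = ForceProtocol(
            mode="apply_release", sense="tension", apply_steps=200, release_steps=200
        )
        integ = IntegratorParams(dt=0.002, seed=2, n_steps=400, save_every=100)
        traj = run_dynamics(config, topo, mech, protocol, integ)
        path = tmp_path / "traj.xyz"
        save_xyz_trajectory(traj, path)
        back = load_xyz_trajectory(path)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-4)
        np.testing.assert_array_equal(back.phase, traj.phase)

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory(
                frames=np.zeros((2, 4, 3)),
                times=np.array([1.0, 1.0]),
                phase=np.array(["free", "free"]),
            )
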