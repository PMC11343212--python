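"""Twist measurement, stretch-stiffness and twist-variance calibration."""

import numpy as np
import pytest

from actinmech.calibration import (
    measure_subunit_twist,
    scan_stiffness,
    scan_twist_stiffness,
    simulate_thermal,
    stretch_stiffness,
    twist_variance_profile,
)
from actinmech.dynamics import Trajectory
from actinmech.lattice import (
    LatticeParams,
    MechanicalParams,
    SpringTopology,
    build_canonical_lattice,
    derive_topology,
)
from actinmech.synth import gen_modulated_lattice, gen_twist_noise_trajectory


class TestMeasureSubunitTwist:
    def test_canonical_lattice_identity(self, canonical100):
        config, _ = canonical100
        twists = measure_subunit_twist(config)
        assert np.abs(twists - (-166.67)).max() < 0.05

    def test_generator_round_trip(self):
        config = build_canonical_lattice(LatticeParams(twist_deg=-160.0, n_subunits=60))
        assert np.abs(measure_subunit_twist(config) + 160.0).max() < 0.05

    def test_linear_twist_gradient_recovered(self):
        lat = gen_modulated_lattice(
            50, twist_modulation=lambda i: -6.0 + 10.0 * i / 48.0
        )  # -166.67 - 6 ... -166.67 + 4: monotone program
        measured = measure_subunit_twist(lat.config)
        programmed = lat.twist_deg[1 : 1 + len(measured)]
        assert np.abs(measured - programmed).max() < 0.5
        assert np.all(np.diff(measured) > 0)

    def test_too_few_subunits(self):
        config = build_canonical_lattice(LatticeParams(n_subunits=4))
        with pytest.raises(ValueError):
            measure_subunit_twist(config)


class TestStretchStiffness:
    def test_serial_chain_closed_form(self):
        """m identical springs in series measure k/m exactly."""
        m_springs = 10
        n = m_springs + 1
        pos = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n) * 2.0])
        topo = SpringTopology(
            bonds=np.column_stack([np.arange(n - 1), np.arange(1, n)]),
            bond_type=np.array(["lateral"] * (n - 1)),
            bond_l0=np.full(n - 1, 2.0),
            angles=np.zeros((0, 3), int),
            angle_theta0=np.zeros(0),
            dihedrals=np.zeros((0, 4), int),
            dihedral_phi0=np.zeros(0),
            dihedral_rest_sines=np.zeros((0, 2)),
            n_subunits=n,
        )
        from actinmech.lattice import FilamentConfiguration

        k = 50.0
        mech = MechanicalParams(k_l=k, k_theta=1e-9, k_phi=1e-9)
        measured = stretch_stiffness(
            topo,
            mech,
            tensions_pn=(2.0, 4.0, 6.0),
            config0=FilamentConfiguration(pos),
            n_fixed=1,
            n_loaded=1,
        )
        assert measured == pytest.approx(k / m_springs, rel=1e-4)

    def test_linearity_under_uniform_stiffness_scaling(self, canonical_39):
        config, topo = canonical_39
        mech = MechanicalParams(300.0, 100.0, 150.0)
        s1 = stretch_stiffness(topo, mech, tensions_pn=(5.0, 15.0, 25.0), config0=config)
        s2 = stretch_stiffness(
            topo, mech.scaled(2.0), tensions_pn=(5.0, 15.0, 25.0), config0=config
        )
        assert s2 == pytest.approx(2.0 * s1, rel=0.02)

    def test_deterministic(self, canonical_39):
        config, topo = canonical_39
        mech = MechanicalParams(300.0, 100.0, 150.0)
        a = stretch_stiffness(topo, mech, tensions_pn=(5.0, 15.0, 25.0), config0=config)
        b = stretch_stiffness(topo, mech, tensions_pn=(5.0, 15.0, 25.0), config0=config)
        assert a == b

    def test_needs_three_tensions(self, canonical_39):
        config, topo = canonical_39
        with pytest.raises(ValueError):
            stretch_stiffness(
                topo, MechanicalParams(300.0, 100.0, 150.0), tensions_pn=(5.0, 10.0)
            )


class TestScanStiffness:
    def test_single_point_grid(self, canonical_39):
        res = scan_stiffness([300.0], [100.0], target_pn_nm=35.0)
        assert res.selected.k_l == 300.0
        assert res.stiffness.shape == (1, 1)
        assert res.selected_stiffness == res.stiffness[0, 0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scan_stiffness([], [100.0], 37.0)


class TestTwistVariance:
    def test_constant_canonical_frames_give_zero_variance(self, canonical100):
        config, _ = canonical100
        frames = np.repeat(config.positions[None], 5, axis=0)
        traj = Trajectory(
            frames=frames,
            times=np.arange(5.0) + 1,
            phase=np.array(["free"] * 5),
        )
        prof = twist_variance_profile(traj)
        # limited only by the sub-0.01 deg bias of the twist estimator
        assert np.all(prof.variance_deg2 < 1e-4)
        assert len(prof.subunit_index) == 60  # 100 subunits minus 2 x 20 terminal

    def test_gaussian_twist_noise_variance_recovered(self):
        # band-limited noise (correlated over a few interfaces, like thermal
        # fluctuations): white noise at the interface Nyquist frequency is
        # partially attenuated by any axis-based twist estimator
        traj = gen_twist_noise_trajectory(
            n_subunits=60, sigma_deg=2.0, n_frames=3000,
            correlation_interfaces=4.0, seed=8,
        )
        prof = twist_variance_profile(traj, exclude_terminal=10)
        assert prof.variance_deg2.mean() == pytest.approx(4.0, rel=0.10)

    def test_cumulative_non_decreasing(self):
        traj = gen_twist_noise_trajectory(n_subunits=60, sigma_deg=3.0, n_frames=200, seed=1)
        prof = twist_variance_profile(traj, exclude_terminal=10)
        assert np.all(np.diff(prof.cumulative_deg2) >= 0)

    def test_single_frame_rejected(self, canonical100):
        config, _ = canonical100
        traj = Trajectory(
            frames=config.positions[None],
            times=np.array([1.0]),
            phase=np.array(["free"]),
        )
        with pytest.raises(ValueError):
            twist_variance_profile(traj)


class TestScanTwistStiffness:
    def test_single_point_grid_selected(self):
        mech_star = MechanicalParams(390.0, 100.0, 150.0)
        ref_traj = simulate_thermal(mech_star, 100, n_steps=20000, save_every=200, seed=3)
        ref = twist_variance_profile(ref_traj, equilibration_frames=10)
        selected, cost = scan_twist_stiffness(
            [150.0], [100.0], ref, k_l=390.0, n_steps=20000, save_every=200, seed=5,
            equilibration_frames=10,
        )
        assert selected.k_phi == 150.0 and selected.k_theta == 100.0
        assert cost.shape == (1, 1)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            scan_twist_stiffness([150.0], [100.0], None, k_l=390.0)

    def test_variance_decreases_with_kphi(self):
        """Stiffer torsion -> smaller per-subunit twist variance."""
        means = []
        for kphi in (75.0, 150.0, 300.0):
            traj = simulate_thermal(
                MechanicalParams(390.0, 100.0, kphi), 100,
                n_steps=30000, save_every=300, seed=2,
            )
            prof = twist_variance_profile(traj, equilibration_frames=20)
            means.append(prof.variance_deg2.mean())
        assert means[0] > means[1] > means[2]


@pytest.fixture(scope="session")
def canonical_39():
    config = build_canonical_lattice(LatticeParams(n_subunits=39))
    return config, derive_topology(config)
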