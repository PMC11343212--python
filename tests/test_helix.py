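"""Helical rise/twist measurement along a variable-radius axis."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from actinmech.calibration import measure_subunit_twist
from actinmech.helix import (
    fit_axis_spline,
    helical_profile,
    instantaneous_rise,
    instantaneous_twist,
    stitch_three,
)
from actinmech.lattice import LatticeParams, build_canonical_lattice
from actinmech.synth import gen_modulated_lattice


class TestAxisSpline:
    def test_canonical_axis_is_straight_with_constant_radius(self, canonical100):
        config, _ = canonical100
        axis = fit_axis_spline(config.positions)
        s = np.linspace(1.0, axis.length_nm - 1.0, 40)
        pts = axis.point(s)
        # straight along z through the origin
        assert np.abs(pts[:, :2]).max() < 0.05
        radius_A = axis.radius(s) * 10.0
        assert np.abs(radius_A - 25.0).max() / 25.0 < 0.02

    def test_collinear_input_returns_line_with_zero_radius(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.arange(20.0)])
        axis = fit_axis_spline(pts)
        s = np.linspace(0, axis.length_nm, 10)
        assert np.abs(axis.radius(s)).max() < 1e-9

    def test_growing_radius_recovered_monotone(self):
        lat = gen_modulated_lattice(60)
        pos = lat.config.positions.copy()
        pos[:, :2] *= (1 + 0.3 * np.arange(60) / 60)[:, None]
        axis = fit_axis_spline(pos)
        s = np.linspace(2.0, axis.length_nm - 2.0, 30)
        r = axis.radius(s)
        assert np.all(np.diff(r) > -1e-3)
        assert r[-1] > r[0] * 1.15

    def test_superhelical_axis_recovered(self):
        lat = gen_modulated_lattice(
            150,
            axis_path=lambda s: np.array(
                [12 * np.sin(2 * np.pi * s / 150), 12 * np.cos(2 * np.pi * s / 150), s]
            ),
        )
        axis = fit_axis_spline(lat.config.positions)
        s = np.linspace(5.0, axis.length_nm - 5.0, 60)
        r = np.linalg.norm(axis.point(s)[:, :2], axis=1)
        assert np.median(r) == pytest.approx(12.0, rel=0.05)

    def test_too_few_centroids(self):
        with pytest.raises(ValueError):
            fit_axis_spline(np.zeros((5, 3)) + np.arange(5)[:, None])


class TestRiseAndTwist:
    def test_canonical_values(self, canonical100):
        config, _ = canonical100
        prof = helical_profile(config.positions)
        assert np.abs(prof.rise_A - 27.8).max() < 0.1
        assert np.abs(prof.twist_deg + 166.67).max() < 0.1

    def test_straight_equally_spaced_points_rise_exact(self):
        pts = np.column_stack([np.zeros(30), np.zeros(30), np.arange(30.0) * 2.5])
        axis = fit_axis_spline(pts)
        rise = instantaneous_rise(pts, axis)
        assert np.allclose(rise, 25.0, atol=1e-6)

    def test_uniform_noncanonical_twist_round_trip(self):
        config = build_canonical_lattice(LatticeParams(twist_deg=-165.0, n_subunits=80))
        prof = helical_profile(config.positions)
        # the residual spiral of the midpoint axis grows as the twist moves
        # away from the canonical value; the mean stays exact
        assert np.abs(prof.twist_deg + 165.0).max() < 0.2
        assert prof.twist_deg.mean() == pytest.approx(-165.0, abs=0.02)

    def test_mirror_image_flips_twist_sign(self, canonical100):
        config, _ = canonical100
        mirrored = config.positions * np.array([1.0, -1.0, 1.0])
        prof = helical_profile(mirrored)
        assert np.abs(prof.twist_deg - 166.67).max() < 0.1

    def test_sinusoidal_rise_modulation_recovered(self):
        lat = gen_modulated_lattice(
            100, rise_modulation=lambda i: 2.0 * np.sin(2 * np.pi * i / 20)
        )
        prof = helical_profile(lat.config.positions)
        assert np.abs(prof.rise_A - lat.rise_A[prof.interface]).max() < 0.3

    def test_sinusoidal_twist_modulation_recovered(self):
        lat = gen_modulated_lattice(
            100, twist_modulation=lambda i: 5.0 * np.sin(2 * np.pi * i / 20)
        )
        prof = helical_profile(lat.config.positions)
        assert np.abs(prof.twist_deg - lat.twist_deg[prof.interface]).max() < 0.2
        # wavelike modulation keeps the canonical value as instantaneous average
        assert prof.twist_deg.mean() == pytest.approx(
            lat.twist_deg[prof.interface].mean(), abs=0.05
        )

    def test_antiphase_strand_rise_keeps_canonical_strand_means(self):
        lat = gen_modulated_lattice(
            100,
            rise_modulation=lambda i: 2.0 * (1 if i % 2 == 0 else -1)
            * np.sin(2 * np.pi * i / 24),
        )
        prof = helical_profile(lat.config.positions)
        for strand in (0, 1):
            mean = prof.rise_A[prof.strand == strand].mean()
            assert mean == pytest.approx(27.8, abs=0.1)

    def test_rigid_motion_invariance(self, canonical100):
        config, _ = canonical100
        rot = Rotation.from_euler("zxz", [0.5, 1.1, -0.3]).as_matrix()
        moved = config.positions @ rot.T + np.array([10.0, -4.0, 6.0])
        prof = helical_profile(moved)
        assert np.abs(prof.rise_A - 27.8).max() < 0.1
        assert np.abs(prof.twist_deg + 166.67).max() < 0.1

    def test_cross_method_twist_consistency(self, canonical100):
        """Midpoint-projection and transported-frame twist agree near canonical."""
        lat = gen_modulated_lattice(
            80, twist_modulation=lambda i: 3.0 * np.sin(2 * np.pi * i / 15)
        )
        n = len(lat.config.positions)
        a_full = np.full(n - 1, np.nan)
        a_full[1 : n - 2] = measure_subunit_twist(lat.config)
        prof = helical_profile(lat.config.positions)
        b_full = np.full(n - 1, np.nan)
        b_full[prof.interface] = prof.twist_deg
        shared = ~np.isnan(a_full) & ~np.isnan(b_full)
        assert shared.sum() > 50
        assert np.abs(a_full[shared] - b_full[shared]).max() < 1.0


class TestStitching:
    def test_three_copy_stitch_triples_length(self, canonical100):
        config, _ = canonical100
        stitched, offset = stitch_three(config.positions)
        assert len(stitched) == 300
        np.testing.assert_allclose(
            stitched[offset : offset + 100], config.positions, atol=1e-9
        )

    def test_stitched_profile_covers_all_central_interfaces(self, canonical100):
        config, _ = canonical100
        prof = helical_profile(config.positions, stitch=True)
        assert len(prof.rise_A) == 99
        assert prof.rise_A.mean() == pytest.approx(27.8, abs=0.01)
        assert prof.twist_deg.mean() == pytest.approx(-166.67, abs=0.05)
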