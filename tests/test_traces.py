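"""Trace splines, PCA alignment, and superhelix statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from actinmech.synth import (
    SyntheticTrace,
    gen_planar_arc_trace,
    gen_straight_trace,
    gen_superhelix_trace,
)
from actinmech.traces import (
    OscillatorySegment,
    curvature_torsion,
    find_oscillatory_segments,
    fit_trace,
    ks_uniformity_test,
    pca_align,
    plane_angle,
    spiral_stats,
)


def analyze(markers, window_nm=350.0):
    trace = fit_trace(markers)
    seg = OscillatorySegment(points=trace.points, step_nm=trace.step_nm)
    aligned = pca_align([seg], window_nm=window_nm)[0]
    return aligned, spiral_stats(aligned)


class TestFitTrace:
    def test_line_resamples_straight_with_zero_curvature(self):
        tr = gen_straight_trace(length_nm=300.0)
        spline = fit_trace(tr.markers)
        kappa, _ = curvature_torsion(spline)
        assert np.abs(kappa[3:-3]).max() < 1e-3
        steps = np.linalg.norm(np.diff(spline.points, axis=0), axis=1)
        assert np.allclose(steps, 0.96, rtol=0.01)

    def test_point_count_matches_arc_length(self):
        tr = gen_straight_trace(length_nm=500.0)
        spline = fit_trace(tr.markers)
        assert len(spline.points) == int(np.floor(500.0 / 0.96)) + 1

    def test_noisy_superhelix_recovered_within_rms(self):
        noisy = gen_superhelix_trace(160.0, 10.0, 10.0, 480.0, noise_nm=1.0, seed=5)
        dense = gen_superhelix_trace(160.0, 10.0, 10.0, 480.0, marker_step_nm=0.5)
        spline = fit_trace(noisy.markers)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(dense.markers).query(spline.points)
        assert np.sqrt(np.mean(d**2)) < 1.0

    def test_duplicate_markers_collapsed_and_minimum_enforced(self):
        markers = np.repeat(gen_straight_trace(40.0).markers[:5], 3, axis=0)
        with pytest.raises(ValueError, match="10"):
            fit_trace(markers)


class TestCurvatureTorsion:
    def test_circle_closed_form(self):
        # radius 0.5 um -> kappa = 2 / um, tau = 0
        tr = gen_planar_arc_trace(curvature_um=2.0, length_nm=400.0)
        kappa, tau = curvature_torsion(fit_trace(tr.markers, smoothing=0.0))
        assert np.median(kappa[5:-5]) == pytest.approx(2.0, rel=0.01)
        assert np.abs(tau[5:-5]).max() < 0.05

    def test_circular_helix_closed_form(self):
        a, lam = 10.0, 160.0
        b = lam / (2 * np.pi)
        tr = gen_superhelix_trace(lam, a, a, 480.0)
        kappa, tau = curvature_torsion(fit_trace(tr.markers, smoothing=0.0))
        assert np.median(kappa[10:-10]) == pytest.approx(a / (a**2 + b**2) * 1e3, rel=0.01)
        assert np.median(np.abs(tau[10:-10])) == pytest.approx(
            b / (a**2 + b**2) * 1e3, rel=0.01
        )

    def test_noisy_arc_within_ten_percent(self):
        # 0.5 nm marker jitter; the default 150 nm^2 smoothing budget absorbs
        # roughly this much over a few hundred markers
        tr = gen_planar_arc_trace(
            curvature_um=1.5, length_nm=400.0, marker_step_nm=2.0, noise_nm=0.5, seed=2
        )
        kappa, _ = curvature_torsion(fit_trace(tr.markers))
        assert np.median(kappa[10:-10]) == pytest.approx(1.5, rel=0.10)


class TestSegmentSelection:
    def test_superhelix_yields_segments_in_length_band(self):
        spline = fit_trace(gen_superhelix_trace(150.0, 25.0, 12.0, 700.0).markers)
        segments = find_oscillatory_segments(spline)
        assert len(segments) >= 1
        for seg in segments:
            assert 350.0 <= seg.length_nm <= 501.0

    def test_straight_trace_yields_none(self):
        spline = fit_trace(gen_straight_trace(700.0).markers)
        assert find_oscillatory_segments(spline) == []


class TestAlignmentAndStats:
    def test_ideal_superhelix_wavelength_amplitude_phase(self):
        _, st = analyze(gen_superhelix_trace(160.0, 10.0, 10.0, 480.0).markers)
        assert st.wavelength_nm == pytest.approx(160.0, abs=2.0)
        assert st.phase_offset == pytest.approx(0.25, abs=0.02)

    def test_elliptical_superhelix_axes(self):
        _, st = analyze(gen_superhelix_trace(160.0, 20.0, 8.0, 480.0).markers)
        assert st.major_axis_nm == pytest.approx(20.0, rel=0.05)
        assert st.minor_axis_nm == pytest.approx(8.0, rel=0.10)
        assert st.phase_offset == pytest.approx(0.25, abs=0.02)
        assert st.significant

    def test_planar_sinusoid_flagged_degenerate(self):
        _, st = analyze(gen_superhelix_trace(160.0, 20.0, 0.0, 480.0).markers)
        assert st.amplitude_pc3_nm < 0.5
        assert st.phase_offset is None

    def test_small_amplitude_flagged_insignificant(self):
        _, st = analyze(gen_superhelix_trace(160.0, 8.0, 5.0, 480.0).markers)
        assert not st.significant

    def test_reversal_and_rigid_motion_invariance(self):
        tr = gen_superhelix_trace(160.0, 20.0, 8.0, 480.0)
        _, st1 = analyze(tr.markers)
        rot = Rotation.from_euler("xyz", [0.4, 1.0, -0.7]).as_matrix()
        moved = (tr.markers @ rot.T + np.array([50.0, -20.0, 90.0]))[::-1]
        _, st2 = analyze(moved)
        assert st2.wavelength_nm == pytest.approx(st1.wavelength_nm, abs=0.5)
        assert st2.amplitude_pc2_nm == pytest.approx(st1.amplitude_pc2_nm, abs=0.1)
        assert st2.phase_offset == pytest.approx(st1.phase_offset, abs=0.02)

    def test_quarter_wavelength_law(self):
        """Noiseless ideal superhelices sit at one-quarter phase offset."""
        for lam, a2, a3 in ((120.0, 14.0, 6.0), (160.0, 10.0, 10.0), (220.0, 18.0, 9.0)):
            _, st = analyze(
                gen_superhelix_trace(lam, a2, a3, 500.0).markers, window_nm=500.0
            )
            assert st.phase_offset == pytest.approx(0.25, abs=0.02), lam

    def test_wavelength_recovery_median_error(self):
        """Median |error| below 5 nm across 100-250 nm with 2 nm noise."""
        errors = []
        for lam in (100.0, 130.0, 160.0, 200.0, 250.0):
            tr = gen_superhelix_trace(lam, 10.0, 10.0, 500.0, noise_nm=2.0, seed=int(lam))
            _, st = analyze(tr.markers, window_nm=500.0)
            errors.append(abs(st.wavelength_nm - lam))
        assert np.median(errors) < 5.0

    def test_flat_pc2_raises(self):
        seg = OscillatorySegment(
            points=gen_straight_trace(400.0).markers, step_nm=4.0
        )
        with pytest.raises(ValueError, match="flat|align"):
            pca_align([seg])


class TestPlaneAngle:
    @pytest.fixture()
    def plane_points(self):
        rng = np.random.default_rng(0)
        # ice plane = x-z plane, containing the filament axis
        return np.column_stack(
            [rng.uniform(-200, 200, 30), rng.normal(0, 0.5, 30), rng.uniform(-200, 200, 30)]
        )

    @pytest.mark.parametrize("tilt,expected", [(0.0, 0.0), (30.0, 30.0), (90.0, 90.0)])
    def test_programmed_tilt_recovered(self, plane_points, tilt, expected):
        tr = gen_superhelix_trace(160.0, 20.0, 8.0, 480.0, tilt_deg=tilt)
        aligned, _ = analyze(tr.markers)
        assert plane_angle(aligned, plane_points) == pytest.approx(expected, abs=2.0)

    def test_collinear_plane_points_rejected(self):
        tr = gen_superhelix_trace(160.0, 20.0, 8.0, 480.0)
        aligned, _ = analyze(tr.markers)
        line = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            plane_angle(aligned, line)


class TestKSTest:
    def test_sample_at_reference_quantiles(self):
        """Points at the (i - 0.5)/n quantiles give D = 0.5/n exactly."""
        from scipy import stats

        n = 20
        sample = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d, _ = ks_uniformity_test(sample, reference_cdf=stats.norm.cdf)
        assert d == pytest.approx(0.5 / n, abs=1e-12)

    def test_matches_brute_force_supremum(self):
        from scipy import stats

        sample = np.array([-1.3, -0.4, 0.1, 0.2, 0.9, 1.1, 1.8, 2.3])
        d, p = ks_uniformity_test(sample, reference_cdf=stats.norm.cdf)
        xs = np.sort(sample)
        cdf = stats.norm.cdf(xs)
        n = len(xs)
        brute = max(
            max(abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i])) for i in range(n)
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_null_samples_rarely_rejected(self):
        rng = np.random.default_rng(1)
        rejections = 0
        trials = 40
        for _ in range(trials):
            sample = rng.normal(size=1000)
            _, p = ks_uniformity_test(sample, mode="standard-normal")
            rejections += p < 0.05
        assert rejections <= 0.12 * trials

    def test_fitted_mode_on_angle_like_sample(self):
        rng = np.random.default_rng(3)
        angles = np.clip(rng.normal(40.0, 15.0, 16), 0, 90)
        d, p = ks_uniformity_test(angles, mode="fitted-normal")
        assert 0.0 <= d <= 1.0 and 0.0 <= p <= 1.0
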