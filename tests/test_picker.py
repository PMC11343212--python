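"""Segmentation-map track extraction and curvature-sensitive picking."""

import numpy as np
import pytest

from actinmech.picker import (
    SegmentationMap,
    classify_superhelical,
    curvature_profile,
    extract_tracks,
    greedy_nms_1d,
    pick_and_suppress,
    read_map,
    write_star,
)
from actinmech.synth import gen_segmentation_image

S_FILAMENT = {
    "start": (150, 30),
    "heading_deg": 90,
    "superhelical": True,
    "segments": [(0.0, 800), (2.0, 300), (-2.0, 300), (2.0, 300), (-2.0, 300), (0.0, 800)],
}
STRAIGHT = {"start": (400, 30), "heading_deg": 90, "segments": [(0.0, 2800)]}
ARC = {"start": (600, 30), "heading_deg": 90, "segments": [(1.0, 2800)]}


@pytest.fixture(scope="module")
def benchmark():
    sim = gen_segmentation_image([S_FILAMENT, STRAIGHT, ARC], shape=(768, 768), seed=1)
    seg = SegmentationMap(sim.image, sim.pixel_size_A)
    return sim, seg, extract_tracks(seg)


class TestExtractTracks:
    def test_blank_map_yields_no_tracks(self):
        seg = SegmentationMap(np.zeros((128, 128)))
        assert extract_tracks(seg) == []

    def test_three_filaments_three_tracks(self, benchmark):
        _, _, tracks = benchmark
        assert len(tracks) == 3
        for t in tracks:
            assert 560 < t.length_px < 720

    def test_crossing_filaments_rejoined(self):
        spec = [
            {"start": (100, 380), "heading_deg": 0, "segments": [(0.0, 2400)]},
            {"start": (380, 100), "heading_deg": 90, "segments": [(0.0, 2400)]},
        ]
        sim = gen_segmentation_image(spec, shape=(768, 768), seed=2)
        tracks = extract_tracks(SegmentationMap(sim.image, sim.pixel_size_A))
        assert len(tracks) == 2
        for t in tracks:
            assert t.length_px > 450  # rejoined across the removed junction

    def test_deterministic(self, benchmark):
        sim, seg, tracks = benchmark
        again = extract_tracks(seg)
        assert len(again) == len(tracks)
        for a, b in zip(tracks, again):
            np.testing.assert_array_equal(a.path_px, b.path_px)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            SegmentationMap(np.full((16, 16), 1.5))


class TestCurvatureProfile:
    def test_straight_track_is_flat(self, benchmark):
        _, seg, tracks = benchmark
        _, kappa = curvature_profile(tracks[1], seg.pixel_size_A)
        assert np.abs(kappa).max() < 0.3

    def test_arc_matches_closed_form(self, benchmark):
        _, seg, tracks = benchmark
        _, kappa = curvature_profile(tracks[2], seg.pixel_size_A)
        assert np.median(kappa) == pytest.approx(1.0, rel=0.05)

    def test_s_filament_sign_change_near_inflection(self, benchmark):
        _, seg, tracks = benchmark
        arcs, kappa = curvature_profile(tracks[0], seg.pixel_size_A)
        strong_pos = arcs[kappa >= 1.5]
        strong_neg = arcs[kappa <= -1.5]
        assert len(strong_pos) and len(strong_neg)
        # programmed first inflection: straight 800 A + arc 300 A from the start
        inflection_px = (800 + 300) / seg.pixel_size_A
        first_neg = strong_neg.min()
        last_pos_before = strong_pos[strong_pos < first_neg].max()
        boundary = 0.5 * (last_pos_before + first_neg)
        assert abs(boundary - inflection_px) < 30

    def test_short_track_yields_empty_profile(self, benchmark):
        _, seg, tracks = benchmark
        import dataclasses

        stub = dataclasses.replace(tracks[0])
        stub.arc_px = stub.arc_px[stub.arc_px < 80]
        arcs, kappa = curvature_profile(stub, seg.pixel_size_A)
        assert len(arcs) == 0 and len(kappa) == 0


class TestClassification:
    def test_benchmark_flags(self, benchmark):
        """All programmed superhelices flagged, no straight/uniplanar ones."""
        sim, seg, tracks = benchmark
        flags = []
        for t in tracks:
            _, kappa = curvature_profile(t, seg.pixel_size_A)
            flags.append(classify_superhelical(kappa, seg.pixel_size_A))
        assert flags == [True, False, False]

    def test_empty_profile_is_not_superhelical(self):
        assert not classify_superhelical(np.array([]))

    def test_run_length_requirement(self):
        # 200 A at 3 px * 4.32 A needs ~16 consecutive samples
        short_run = np.concatenate([np.full(10, 2.0), np.full(30, -2.0)])
        assert not classify_superhelical(short_run)
        long_runs = np.concatenate([np.full(20, 2.0), np.full(20, -2.0)])
        assert classify_superhelical(long_runs)


class TestNMS:
    def test_greedy_example(self):
        positions = np.arange(0, 1001, 100.0)
        kept = greedy_nms_1d(positions, 830.0)
        np.testing.assert_array_equal(positions[kept], [0.0, 900.0])

    def test_single_pick_retained(self):
        assert list(greedy_nms_1d(np.array([123.0]), 830.0)) == [0]

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            pos = np.sort(rng.uniform(0, 3000, rng.integers(2, 12)))
            kept = greedy_nms_1d(pos, 830.0)
            # brute-force greedy-from-first reference
            ref = [0]
            for i in range(1, len(pos)):
                if pos[i] - pos[ref[-1]] >= 830.0:
                    ref.append(i)
            assert list(kept) == ref
            assert np.all(np.diff(pos[kept]) >= 830.0)

    def test_per_filament_rule_and_star_output(self, benchmark, tmp_path):
        sim, seg, tracks = benchmark
        table = pick_and_suppress(tracks, seg)
        df = table.to_frame()
        assert set(df.filament_id) == {0}  # only the S-filament is picked
        for _, group in df.groupby("filament_id"):
            arcs = np.sort(group.segment_index.to_numpy() * 100.0)
            assert np.all(np.diff(arcs) >= 830.0 - 1e-9)
        star = tmp_path / "picks.star"
        write_star(table, star)
        text = star.read_text()
        assert "_rlnCoordinateX" in text and "_rlnHelicalTubeID" in text
        assert len(text.strip().splitlines()) == 7 + len(df)


class TestMapIO:
    def test_tiff_round_trip(self, tmp_path, benchmark):
        import tifffile

        sim, _, _ = benchmark
        path = tmp_path / "map.tiff"
        tifffile.imwrite(path, sim.image.astype(np.float32))
        seg = read_map(path, pixel_size_A=4.32)
        assert seg.data.shape == sim.image.shape
        np.testing.assert_allclose(seg.data, sim.image, atol=1e-6)
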