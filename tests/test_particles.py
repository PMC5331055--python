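import math

import numpy as np
import pytest

import chromatrack as ct
from chromatrack.errors import LookupError_
from chromatrack.detection import SpotDetection
from chromatrack.particles import (ParticleConfig, analyze_particles,
                                   make_search_region, measure_all,
                                   measure_track_frame, track_center)
from chromatrack.tracking import Track
from conftest import (crack_perimeter_oracle, disk_pixel_count_oracle,
                      flood_fill_components, match_tracks_to_truth)


def test_filled_square_area_perimeter_circularity():
    mask = np.zeros((9, 9), dtype=bool)
    mask[2:7, 2:7] = True
    (p,) = analyze_particles(mask)
    assert p.area == 25
    assert p.perimeter == 20
    assert p.circularity == pytest.approx(math.pi / 4)  # 4*pi*25/400


def test_diagonal_pixels_are_one_particle_under_8_connectivity():
    mask = np.zeros((4, 4), dtype=bool)
    mask[1, 1] = mask[2, 2] = True
    parts = analyze_particles(mask)
    assert len(parts) == 1
    assert parts[0].area == 2


def test_labeling_matches_flood_fill_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        mask = rng.random((16, 16)) < rng.uniform(0.2, 0.6)
        parts = analyze_particles(mask)
        oracle = flood_fill_components(mask)
        assert len(parts) == len(oracle)
        got = {frozenset(map(tuple, p.pixels)) for p in parts}
        assert got == set(oracle)
        for p in parts:
            assert p.perimeter == crack_perimeter_oracle(p.pixels)


def test_disk_circularity_follows_crack_formula():
    # crack-boundary perimeter of a digital disk is ~8r (2*(w+h)), so its
    # circularity tends to pi^2/16 ~ 0.617, below the pi/4 ceiling
    yy, xx = np.mgrid[0:32, 0:32]
    mask = (xx - 15) ** 2 + (yy - 15) ** 2 <= 100
    (p,) = analyze_particles(mask)
    assert p.perimeter == crack_perimeter_oracle(p.pixels)
    assert p.circularity == pytest.approx(
        4 * math.pi * p.area / p.perimeter ** 2)
    assert 0.5 < p.circularity < math.pi / 4


def test_crack_circularity_never_exceeds_pi_over_4():
    # for any pixel set, crack perimeter >= 4*sqrt(area), so
    # 4*pi*A/p^2 <= pi/4; the clamp at 1 is therefore never reached
    rng = np.random.default_rng(5)
    for _ in range(50):
        mask = rng.random((12, 12)) < 0.5
        for p in analyze_particles(mask):
            assert p.circularity <= math.pi / 4 + 1e-12


def test_area_circularity_filters():
    mask = np.zeros((20, 20), dtype=bool)
    mask[1:4, 1:4] = True            # 3x3 square, area 9
    mask[10, 1:15] = True            # 1x14 line, low circularity
    parts = analyze_particles(mask, ParticleConfig(min_area=5))
    assert len(parts) == 2
    parts = analyze_particles(mask, ParticleConfig(min_circularity=0.5))
    assert len(parts) == 1 and parts[0].area == 9


@pytest.mark.parametrize("spot,offset,expected", [
    ((50, 50, 5), 10, (35, 35, 31, 31)),
    ((2, 2, 5), 10, (0, 0, 18, 18)),   # clamped at the frame corner
    ((50, 50, 5), 0, (45, 45, 11, 11)),  # box exactly bounding the circle
])
def test_search_region_geometry(spot, offset, expected):
    x, y, r = spot
    rect = make_search_region(x, y, r, offset, 128, 128)
    assert (rect.x0, rect.y0, rect.width, rect.height) == expected


def one_spot_setup(cx=30.0, cy=30.0, r=5.0, shape=(64, 64),
                   color=(120, 30, 40)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    colorframe = np.full((*shape, 3), 220, dtype=np.uint8)
    colorframe[mask] = color
    track = Track(1, {0: SpotDetection(0, cx, cy, r, 1.0)})
    return track, mask, colorframe


def test_disk_measurement_matches_rasterization_oracle():
    track, mask, colorframe = one_spot_setup()
    cell = measure_track_frame(track, 0, mask, colorframe)
    assert cell.status == "measured"
    assert cell.area == disk_pixel_count_oracle(30.0, 30.0, 5.0)
    assert cell.rgb == (120, 30, 40)


def test_pure_red_disk_color_is_exact():
    track, mask, colorframe = one_spot_setup(color=(255, 0, 0))
    cell = measure_track_frame(track, 0, mask, colorframe)
    assert cell.rgb == (255, 0, 0)


def test_tight_roi_flags_boundary_touch():
    track, mask, colorframe = one_spot_setup()
    cfg = ParticleConfig(roi_offset=0)
    # offset 0 makes the ROI exactly bound the nominal circle, so the
    # rasterized disk touches the box
    cell = measure_track_frame(track, 0, mask, colorframe, cfg)
    assert cell.status == "boundary_touch"
    assert cell.area is not None  # flagged, but still reported


def test_frame_outside_track_is_error():
    track, mask, colorframe = one_spot_setup()
    with pytest.raises(LookupError_):
        measure_track_frame(track, 5, mask, colorframe)


def test_gap_center_is_linear_interpolation():
    track = Track(1, {0: SpotDetection(0, 10.0, 20.0, 5.0, 1.0),
                      4: SpotDetection(4, 18.0, 28.0, 5.0, 1.0)},
                  gap_spans=[(1, 3)])
    x, y, r = track_center(track, 2)
    assert (x, y) == (14.0, 24.0)
    assert r == 5.0


def test_measure_all_row_contract_with_gap():
    cfg = ct.SceneConfig(seed=5, n_spots=1, n_frames=12,
                         occlusions=[(1, 5, 2)])
    stack, truth = ct.generate_video(cfg)
    res = ct.run_pipeline(ct.RunConfig(), stack=stack)
    (track,) = res.tracks
    rows = [c for c in res.measurements if c.track_id == track.track_id]
    assert len(rows) == track.last_frame - track.first_frame + 1
    assert {c.frame_index for c in rows} == set(
        range(track.first_frame, track.last_frame + 1))


def test_end_to_end_areas_and_colors_exact(noiseless_result, noiseless_scene):
    stack, truth = noiseless_scene
    res = noiseless_result
    mapping = match_tracks_to_truth(res.tracks, truth)
    assert len(res.measurements) == truth.n_spots * stack.n_frames
    for cell in res.measurements:
        s = truth.spot(mapping[cell.track_id])
        assert cell.status == "measured"
        assert cell.area == ct.truth_area(truth, s.spot_id, cell.frame_index)
        assert cell.rgb == s.color


def test_area_series_tracks_radius_dynamics():
    cfg = ct.SceneConfig(seed=8, n_spots=1, radius_dynamics="sigmoid_expand",
                         r_min=2.0, r_max=8.0, onset_frame=20.0)
    stack, truth = ct.generate_video(cfg)
    res = ct.run_pipeline(ct.RunConfig(), stack=stack)
    track = max(res.tracks, key=len)
    measured = [res.measurements.get(track.track_id, f).area
                for f in range(cfg.n_frames)]
    expected = [math.pi * truth.spots[0].radii[f] ** 2
                for f in range(cfg.n_frames)]
    r = np.corrcoef(measured, expected)[0, 1]
    assert r >= 0.99
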