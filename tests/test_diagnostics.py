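import numpy as np
import pytest

import chromatrack as ct
from chromatrack.diagnostics import (auto_repair, delete_track,
                                     diagnose_tracks, update_roi)
from chromatrack.errors import LookupError_
from chromatrack.particles import ParticleConfig
from chromatrack.video_io import Rect
from conftest import disk_pixel_count_oracle


@pytest.fixture()
def tight_roi_run():
    """A run whose ROI exactly bounds the disks, forcing boundary_touch."""
    cfg = ct.SceneConfig(seed=9, n_spots=3, n_frames=8)
    stack, truth = ct.generate_video(cfg)
    rc = ct.RunConfig()
    rc.particles = ParticleConfig(roi_offset=0)
    res = ct.run_pipeline(rc, stack=stack)
    return stack, truth, res


def test_clean_run_has_no_missing_cells(noiseless_result):
    report = diagnose_tracks(noiseless_result.measurements)
    assert report.tracks_with_missing == []
    assert report.missing_cells == []
    assert all(v == 50 for v in report.per_track_spot_counts.values())


def test_diagnose_lists_every_flagged_cell(tight_roi_run):
    _, _, res = tight_roi_run
    report = diagnose_tracks(res.measurements)
    assert len(report.missing_cells) >= 1
    assert report.tracks_with_missing == sorted(
        {t for t, _, _ in report.missing_cells})
    for tid, f, status in report.missing_cells:
        assert res.measurements.get(tid, f).status == status != "measured"


def test_occlusion_schedule_shows_up_in_diagnosis():
    # centers far enough apart that an occluded spot's search region never
    # contains a neighboring particle
    cfg = ct.SceneConfig(seed=4, n_spots=4, occlusions=[(1, 20, 2),
                                                        (2, 30, 2)],
                         centers=[(20.0, 20.0), (108.0, 20.0),
                                  (20.0, 108.0), (108.0, 108.0)])
    stack, truth = ct.generate_video(cfg)
    res = ct.run_pipeline(ct.RunConfig(), stack=stack)
    report = diagnose_tracks(res.measurements)
    flagged = {(t, f) for t, f, _ in report.missing_cells}
    occluded_frames = {f for s in truth.spots for f in s.occluded}
    assert {f for _, f in flagged} == occluded_frames


def test_update_roi_repairs_boundary_touch_to_oracle_area(tight_roi_run):
    stack, truth, res = tight_roi_run
    report = diagnose_tracks(res.measurements)
    tid, f, status = report.missing_cells[0]
    assert status == "boundary_touch"
    old = res.measurements.get(tid, f)
    grown = Rect(old.roi.x0 - 5, old.roi.y0 - 5,
                 old.roi.width + 10, old.roi.height + 10)
    cell = update_roi(res.measurements, tid, f, grown,
                      res.binary_stack[f], stack.frames[f])
    assert cell.status == "measured"
    cx, cy = old.center
    best = min(truth.spots, key=lambda s: (s.centers[f, 0] - cx) ** 2
               + (s.centers[f, 1] - cy) ** 2)
    assert cell.area == disk_pixel_count_oracle(
        best.centers[f, 0], best.centers[f, 1], best.radii[f])


def test_update_roi_is_idempotent(noiseless_result, noiseless_scene):
    stack, _ = noiseless_scene
    res = noiseless_result
    tid = res.measurements.track_ids[0]
    before = res.measurements.get(tid, 0)
    cell = update_roi(res.measurements, tid, 0, before.roi,
                      res.binary_stack[0], stack.frames[0])
    assert cell.status == before.status
    assert cell.area == before.area
    assert cell.rgb == before.rgb


def test_update_roi_away_from_spot_reports_missing(tight_roi_run):
    stack, _, res = tight_roi_run
    tid = res.measurements.track_ids[0]
    f = 0
    far = Rect(0, 0, 3, 3)  # corner region with no particle
    cell = update_roi(res.measurements, tid, f, far,
                      res.binary_stack[f], stack.frames[f])
    assert cell.status == "missing"


def test_unknown_cell_is_lookup_error(noiseless_result, noiseless_scene):
    stack, _ = noiseless_scene
    with pytest.raises(LookupError_):
        update_roi(noiseless_result.measurements, 999, 0, Rect(0, 0, 5, 5),
                   noiseless_result.binary_stack[0], stack.frames[0])


def test_delete_track_removes_only_that_track():
    cfg = ct.SceneConfig(seed=2, n_spots=5, n_frames=6)
    stack, _ = ct.generate_video(cfg)
    res = ct.run_pipeline(ct.RunConfig(), stack=stack)
    victim = res.tracks[2].track_id
    others_before = {(c.track_id, c.frame_index): (c.area, c.rgb)
                     for c in res.measurements if c.track_id != victim}
    kept = delete_track(res.tracks, res.measurements, victim)
    assert [t.track_id for t in kept] == [t for t in range(1, 6)
                                          if t != victim]
    report = diagnose_tracks(res.measurements)
    assert victim not in report.per_track_spot_counts
    others_after = {(c.track_id, c.frame_index): (c.area, c.rgb)
                    for c in res.measurements}
    assert others_after == others_before
    with pytest.raises(LookupError_):
        delete_track(kept, res.measurements, victim)


def test_auto_repair_reduces_missing_cells(tight_roi_run):
    stack, _, res = tight_roi_run
    before = len(diagnose_tracks(res.measurements).missing_cells)
    assert before > 0
    fixed = auto_repair(res.tracks, res.measurements, res.binary_stack,
                        stack.frames, ParticleConfig(roi_offset=0))
    after = len(diagnose_tracks(res.measurements).missing_cells)
    assert fixed > 0
    assert after < before
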