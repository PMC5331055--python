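import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import chromatrack as ct
from chromatrack.detection import SpotDetection
from chromatrack.tracking import (Track, TrackingConfig, build_tracks,
                                  close_gaps, link_frames,
                                  tracks_to_dataframe)
from conftest import brute_force_assignment, match_tracks_to_truth


def det(frame, x, y, q=1.0):
    return SpotDetection(frame, float(x), float(y), 5.0, q)


def segment(points):
    """points: {frame: (x, y)}"""
    return Track(0, {f: det(f, x, y) for f, (x, y) in points.items()})


def test_stationary_detection_chains_into_one_segment():
    dets = [det(f, 50, 50) for f in range(10)]
    segs = link_frames(dets, TrackingConfig())
    assert len(segs) == 1
    assert sorted(segs[0].detections) == list(range(10))


def test_jump_beyond_cap_never_links():
    dets = [det(f, 20 * f, 10) for f in range(5)]  # 20 px/frame > 15
    segs = link_frames(dets, TrackingConfig(linking_max_distance=15))
    assert len(segs) == 5
    assert all(len(s) == 1 for s in segs)


@pytest.mark.parametrize("seed", range(10))
def test_linking_cost_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_a, n_b = rng.integers(1, 5), rng.integers(1, 5)
    a = rng.uniform(0, 40, (n_a, 2))
    b = rng.uniform(0, 40, (n_b, 2))
    cap = 15.0
    dets = ([det(0, x, y) for x, y in a] + [det(1, x, y) for x, y in b])
    segs = link_frames(dets, TrackingConfig(linking_max_distance=cap))
    links = []
    for s in segs:
        if 0 in s.detections and 1 in s.detections:
            d0, d1 = s.detections[0], s.detections[1]
            links.append((d1.x - d0.x) ** 2 + (d1.y - d0.y) ** 2)
    card, cost = brute_force_assignment(a, b, cap)
    assert len(links) == card
    assert sum(links) == pytest.approx(cost, rel=1e-9)


def test_crossing_spots_assignment_is_minimal():
    # two spots swap corners; staying put is cheaper than crossing
    a = [(10.0, 10.0), (20.0, 10.0)]
    b = [(12.0, 10.0), (22.0, 10.0)]
    dets = ([det(0, x, y) for x, y in a] + [det(1, x, y) for x, y in b])
    segs = link_frames(dets, TrackingConfig())
    assert len(segs) == 2
    for s in segs:
        d0, d1 = s.detections[0], s.detections[1]
        assert abs(d1.x - d0.x) == 2.0


def test_gap_of_two_frames_is_closed_with_span():
    a = segment({f: (50, 50) for f in range(4)})       # ends frame 3
    b = segment({f: (50, 50) for f in (6, 7)})         # restarts frame 6
    tracks = close_gaps([a, b], TrackingConfig(max_frame_gap=2))
    assert len(tracks) == 1
    assert tracks[0].gap_spans == [(4, 5)]
    assert sorted(tracks[0].detections) == [0, 1, 2, 3, 6, 7]


def test_gap_of_three_frames_is_not_closed():
    a = segment({f: (50, 50) for f in range(4)})
    b = segment({f: (50, 50) for f in (7, 8)})         # 3 missing frames
    tracks = close_gaps([a, b], TrackingConfig(max_frame_gap=2))
    assert len(tracks) == 2


@pytest.mark.parametrize("dx,merged", [(15.0, True), (15.1, False)])
def test_gap_closing_distance_cap_is_inclusive(dx, merged):
    a = segment({f: (50.0, 50.0) for f in range(4)})
    b = segment({f: (50.0 + dx, 50.0) for f in (6, 7)})
    tracks = close_gaps([a, b], TrackingConfig())
    assert (len(tracks) == 1) == merged


def test_track_ids_renumbered_by_first_appearance():
    b = segment({5: (10, 10)})
    a = segment({0: (90, 90), 1: (90, 90)})
    c = segment({0: (10, 20)})
    tracks = close_gaps([b, a, c], TrackingConfig(max_frame_gap=0))
    order = [(t.first_frame, t.first_detection.y, t.first_detection.x)
             for t in tracks]
    assert order == sorted(order)
    assert [t.track_id for t in tracks] == [1, 2, 3]


def test_detection_conservation_and_caps_on_synthetic(noiseless_scene):
    stack, truth = noiseless_scene
    res = ct.run_pipeline(ct.RunConfig(), stack=stack)
    n_linked = sum(len(t) for t in res.tracks)
    assert n_linked == res.manifest["n_detections"]
    cfg = TrackingConfig()
    for t in res.tracks:
        frames = t.frames
        for f0, f1 in zip(frames, frames[1:]):
            d0, d1 = t.detections[f0], t.detections[f1]
            dist = np.hypot(d1.x - d0.x, d1.y - d0.y)
            if f1 - f0 == 1:
                assert dist <= cfg.linking_max_distance
            else:
                assert f1 - f0 <= cfg.max_frame_gap + 1
                assert dist <= cfg.gap_closing_max_distance


def test_occlusion_track_count_and_identity(noiseless_scene):
    stack, truth = noiseless_scene
    res = ct.run_pipeline(ct.RunConfig(), stack=stack)
    assert len(res.tracks) == truth.n_spots
    mapping = match_tracks_to_truth(res.tracks, truth)
    assert len(set(mapping.values())) == truth.n_spots  # no identity clashes
    # zero identity switches: every detection stays nearest its own spot
    for t in res.tracks:
        sid = mapping[t.track_id]
        s = truth.spot(sid)
        for f, d in t.detections.items():
            assert np.hypot(d.x - s.centers[f, 0],
                            d.y - s.centers[f, 1]) <= 2.0


@given(st.integers(0, 2**31 - 1))
def test_partition_invariant_under_input_permutation(seed):
    rng = np.random.default_rng(seed)
    dets = []
    for f in range(4):
        for _ in range(rng.integers(1, 5)):
            dets.append(det(f, rng.uniform(0, 60), rng.uniform(0, 60)))
    cfg = TrackingConfig()
    base = build_tracks(dets, cfg)
    perm = list(dets)
    rng.shuffle(perm)
    other = build_tracks(perm, cfg)
    as_sets = lambda ts: sorted(
        sorted((f, d.x, d.y) for f, d in t.detections.items()) for t in ts)
    assert as_sets(base) == as_sets(other)
    assert [t.track_id for t in base] == [t.track_id for t in other]


def test_tracks_serialize_to_flat_csv(tmp_path):
    tracks = close_gaps([segment({0: (1, 2), 1: (3, 4)})], TrackingConfig())
    df = tracks_to_dataframe(tracks)
    assert list(df.columns) == ["track_id", "frame", "x", "y", "radius",
                                "quality"]
    p = tmp_path / "tracks.csv"
    df.to_csv(p, index=False)
    import pandas as pd
    assert pd.read_csv(p).shape == (2, 6)
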