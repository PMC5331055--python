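"""Frame-to-frame linking and gap closing.

Detections are chained into tracks by solving, for each consecutive frame
pair, an exact minimum-cost one-to-one assignment (Hungarian) with squared
Euclidean distance costs and a hard distance cap; track fragments separated
by short occlusions are then merged by a second assignment between segment
ends and later segment starts. Tracks are simple chains — no splitting or
merging events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import SpotDetection
from .errors import ConfigError

__all__ = ["Track", "TrackingConfig", "link_frames", "close_gaps",
           "build_tracks", "tracks_to_dataframe"]


@dataclass
class TrackingConfig:
    """Distance/gap caps for linking, with the classic tracking defaults.

    max_frame_gap is the maximum number of consecutive missing frames a
    track may bridge: a segment ending at frame e may be joined to one
    starting at frame s when ``2 <= s - e <= max_frame_gap + 1``.
    """

    linking_max_distance: float = 15.0
    gap_closing_max_distance: float = 15.0
    max_frame_gap: int = 2
    initial_quality_filter: float = 0.0

    def __post_init__(self) -> None:
        if self.linking_max_distance < 0 or self.gap_closing_max_distance < 0:
            raise ConfigError("distance caps must be >= 0")
        if self.max_frame_gap < 0:
            raise ConfigError("max_frame_gap must be >= 0")


@dataclass
class Track:
    """A uniquely numbered temporal chain of detections.

    ``detections`` maps frame index -> detection, at most one per frame.
    ``gap_spans`` records inclusive (start, end) frame ranges that were
    bridged by gap closing (frames with no detection).
    """

    track_id: int
    detections: dict[int, SpotDetection] = field(default_factory=dict)
    gap_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return sorted(self.detections)

    @property
    def first_frame(self) -> int:
        return min(self.detections)

    @property
    def last_frame(self) -> int:
        return max(self.detections)

    @property
    def first_detection(self) -> SpotDetection:
        return self.detections[self.first_frame]

    @property
    def last_detection(self) -> SpotDetection:
        return self.detections[self.last_frame]

    def __len__(self) -> int:
        return len(self.detections)


def _capped_assignment(src: np.ndarray, dst: np.ndarray,
                       max_distance: float) -> list[tuple[int, int]]:
    """Min-cost one-to-one matching under a hard distance cap.

    Pairs farther apart than the cap are forbidden. Among matchings that use
    only allowed pairs, the solution has maximum cardinality and, among
    those, minimum total squared distance (forbidden entries carry a cost
    larger than any feasible total, so the exact solver never trades a real
    link away).
    """
    if len(src) == 0 or len(dst) == 0:
        return []
    d2 = ((src[:, None, :] - dst[None, :, :]) ** 2).sum(axis=2)
    cap_sq = float(max_distance) ** 2
    allowed = d2 <= cap_sq
    if not allowed.any():
        return []
    big = cap_sq * min(len(src), len(dst)) + 1.0
    cost = np.where(allowed, d2, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if allowed[r, c]]


def _group_by_frame(detections) -> dict[int, list[SpotDetection]]:
    if isinstance(detections, dict):
        return {int(f): list(ds) for f, ds in detections.items()}
    flat: list[SpotDetection] = []
    for item in detections:
        if isinstance(item, SpotDetection):
            flat.append(item)
        else:
            flat.extend(item)
    grouped: dict[int, list[SpotDetection]] = {}
    for d in flat:
        grouped.setdefault(d.frame_index, []).append(d)
    return grouped


def link_frames(detections, config: TrackingConfig) -> list[Track]:
    """Link per-frame detections into pre-gap-closing segments.

    ``detections`` may be a flat iterable of SpotDetection, a sequence of
    per-frame lists, or a frame -> detections dict. Segment ids are assigned
    in order of first appearance (frame, then y, then x); the result is
    deterministic and independent of within-frame input order.
    """
    grouped = _group_by_frame(detections)
    segments: list[list[SpotDetection]] = []
    active: dict[int, int] = {}  # segment index -> frame of its last detection
    frames = sorted(grouped)
    for f in frames:
        dets = sorted(grouped[f], key=lambda d: (d.y, d.x))
        prev_segs = [s for s, lf in active.items() if lf == f - 1]
        prev_segs.sort(key=lambda s: (segments[s][-1].y, segments[s][-1].x))
        matched_dst: set[int] = set()
        if prev_segs and dets:
            src = np.array([[segments[s][-1].x, segments[s][-1].y]
                            for s in prev_segs])
            dst = np.array([[d.x, d.y] for d in dets])
            for r, c in _capped_assignment(src, dst,
                                           config.linking_max_distance):
                seg = prev_segs[r]
                segments[seg].append(dets[c])
                active[seg] = f
                matched_dst.add(c)
        for c, d in enumerate(dets):
            if c not in matched_dst:
                segments.append([d])
                active[len(segments) - 1] = f
    return [Track(track_id=i + 1, detections={d.frame_index: d for d in seg})
            for i, seg in enumerate(segments)]


def close_gaps(segments: Sequence[Track], config: TrackingConfig) -> list[Track]:
    """Merge segments across short occlusions and renumber tracks.

    A segment end may connect to a later segment start when the frame
    difference is in [2, max_frame_gap + 1] and the Euclidean distance is
    within the (inclusive) gap-closing cap; connections are chosen by an
    exact min-cost assignment and merged transitively. Final ids run 1..N
    ordered by (first frame, y, x) of the first detection.
    """
    segs = list(segments)
    n = len(segs)
    link_to: dict[int, int] = {}
    if n and config.max_frame_gap > 0:
        ends = np.array([[s.last_detection.x, s.last_detection.y]
                         for s in segs])
        starts = np.array([[s.first_detection.x, s.first_detection.y]
                           for s in segs])
        d2 = ((ends[:, None, :] - starts[None, :, :]) ** 2).sum(axis=2)
        dframe = np.array([[segs[j].first_frame - segs[i].last_frame
                            for j in range(n)] for i in range(n)])
        cap_sq = float(config.gap_closing_max_distance) ** 2
        allowed = ((dframe >= 2) & (dframe <= config.max_frame_gap + 1)
                   & (d2 <= cap_sq))
        if allowed.any():
            big = cap_sq * n + 1.0
            cost = np.where(allowed, d2, big)
            rows, cols = linear_sum_assignment(cost)
            link_to = {int(r): int(c) for r, c in zip(rows, cols)
                       if allowed[r, c]}

    merged_into = set(link_to.values())
    tracks: list[Track] = []
    for i in range(n):
        if i in merged_into:
            continue
        detections = dict(segs[i].detections)
        gap_spans = list(segs[i].gap_spans)
        j = i
        while j in link_to:
            k = link_to[j]
            gap_spans.append((segs[j].last_frame + 1,
                              segs[k].first_frame - 1))
            detections.update(segs[k].detections)
            gap_spans.extend(segs[k].gap_spans)
            j = k
        tracks.append(Track(track_id=0, detections=detections,
                            gap_spans=sorted(gap_spans)))

    tracks.sort(key=lambda t: (t.first_frame, t.first_detection.y,
                               t.first_detection.x))
    for new_id, t in enumerate(tracks, start=1):
        t.track_id = new_id
    return tracks


def build_tracks(detections, config: TrackingConfig | None = None) -> list[Track]:
    """Convenience: link frames then close gaps with one config."""
    config = config or TrackingConfig()
    return close_gaps(link_frames(detections, config), config)


def tracks_to_dataframe(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flat (track_id, frame, x, y, radius, quality) table for CSV export."""
    rows = [
        {"track_id": t.track_id, "frame": f, "x": d.x, "y": d.y,
         "radius": d.radius, "quality": d.quality}
        for t in tracks for f, d in sorted(t.detections.items())
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y",
                                       "radius", "quality"])
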