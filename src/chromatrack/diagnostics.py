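"""Track diagnosis and repair.

Scriptable equivalents of the interactive post-analysis workflow: report
tracks with missing or unreliable per-frame measurements, re-measure a cell
inside a user-supplied ROI, drop bad tracks, and a batch auto-repair that
retries missing cells with progressively larger ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import LookupError_
from .particles import (STATUS_BOUNDARY, STATUS_MEASURED, FrameMeasurement,
                        ParticleConfig, TrackMeasurements, measure_region,
                        track_center)
from .tracking import Track
from .video_io import Rect

__all__ = ["DiagnosisReport", "diagnose_tracks", "update_roi", "delete_track",
           "auto_repair"]


@dataclass
class DiagnosisReport:
    """Spot counts per track and the cells that still lack a clean measurement."""

    per_track_spot_counts: dict[int, int]
    tracks_with_missing: list[int]
    missing_cells: list[tuple[int, int, str]]  # (track_id, frame, status)

    @property
    def n_tracks(self) -> int:
        return len(self.per_track_spot_counts)

    def to_records(self) -> list[dict]:
        return [{"track_id": t, "frame": f, "status": s}
                for t, f, s in self.missing_cells]


def diagnose_tracks(measurements: TrackMeasurements) -> DiagnosisReport:
    """Count cleanly measured frames per track and list every other cell."""
    counts: dict[int, int] = {tid: 0 for tid in measurements.track_ids}
    missing: list[tuple[int, int, str]] = []
    for cell in measurements:
        if cell.status == STATUS_MEASURED:
            counts[cell.track_id] += 1
        else:
            missing.append((cell.track_id, cell.frame_index, cell.status))
    with_missing = sorted({t for t, _, _ in missing})
    return DiagnosisReport(per_track_spot_counts=counts,
                           tracks_with_missing=with_missing,
                           missing_cells=missing)


def update_roi(measurements: TrackMeasurements, track_id: int,
               frame_index: int, new_region: Rect, binary_frame,
               color_frame, config: ParticleConfig | None = None
               ) -> FrameMeasurement:
    """Re-run particle analysis for one cell inside ``new_region``.

    The repaired cell replaces the stored one. A measurement only upgrades
    to 'measured' when the selected particle keeps at least a one-pixel gap
    to the region on all sides; a particle touching the region border stays
    flagged 'boundary_touch'.
    """
    config = config or ParticleConfig()
    old = measurements.get(track_id, frame_index)
    cell = measure_region(track_id, frame_index, old.center, new_region,
                          binary_frame, color_frame, config)
    measurements.put(cell)
    return cell


def delete_track(tracks: Sequence[Track], measurements: TrackMeasurements,
                 track_id: int) -> list[Track]:
    """Remove a track and all its measurement rows; other ids are untouched."""
    kept = [t for t in tracks if t.track_id != track_id]
    if len(kept) == len(list(tracks)):
        raise LookupError_(f"unknown track id {track_id}")
    measurements.drop_track(track_id)
    return kept


def auto_repair(tracks: Sequence[Track], measurements: TrackMeasurements,
                binary_stack, color_stack,
                config: ParticleConfig | None = None,
                growth: float = 0.25, max_retries: int = 3) -> int:
    """Retry every non-measured cell with an ROI enlarged by ``growth`` per
    attempt (batch stand-in for stepping through frames by hand).

    Returns the number of cells repaired to 'measured'.
    """
    config = config or ParticleConfig()
    by_id = {t.track_id: t for t in tracks}
    repaired = 0
    for tid, f, _status in diagnose_tracks(measurements).missing_cells:
        track = by_id.get(tid)
        if track is None:
            continue
        old = measurements.get(tid, f)
        x, y = old.center
        _, _, radius = track_center(track, f)
        base_half = max(old.roi.width, old.roi.height) // 2
        for attempt in range(1, max_retries + 1):
            half = int(round(base_half * (1.0 + growth * attempt)))
            region = Rect(int(round(x)) - half, int(round(y)) - half,
                          2 * half + 1, 2 * half + 1)
            cell = update_roi(measurements, tid, f, region,
                              binary_stack[f], color_stack[f], config)
            if cell.status == STATUS_MEASURED:
                repaired += 1
                break
    return repaired
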