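"""Connected-component particle analysis and per-track measurement.

For every tracked spot and frame, a square search region (ROI) around the
tracked center is scanned in the thresholded image; the spot's connected
particle is selected and measured for area (px²), perimeter, circularity and
the RGB color at the spot center.

Conventions, used everywhere:

* components are 8-connected;
* perimeter is the crack-boundary edge count — the number of pixel edges
  separating foreground from background (or from outside the region);
* circularity = min(1, 4·pi·area / perimeter²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ConfigError, LookupError_
from .tracking import Track
from .video_io import Rect

__all__ = ["Particle", "ParticleConfig", "FrameMeasurement",
           "TrackMeasurements", "make_search_region", "analyze_particles",
           "measure_track_frame", "measure_all", "track_center"]

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

STATUS_MEASURED = "measured"
STATUS_MISSING = "missing"
STATUS_BOUNDARY = "boundary_touch"


@dataclass
class Particle:
    """One connected foreground region.

    ``pixels`` is an (N, 2) integer array of (x, y) coordinates in the frame
    of reference the mask was analyzed in (callers offset to full-frame
    coordinates when the mask was an ROI crop).
    """

    pixels: np.ndarray
    area: int
    perimeter: int
    circularity: float
    centroid: tuple[float, float]
    bbox: Rect

    def contains(self, x: int, y: int) -> bool:
        return bool(((self.pixels[:, 0] == x) & (self.pixels[:, 1] == y)).any())

    def shifted(self, dx: int, dy: int) -> "Particle":
        return Particle(
            pixels=self.pixels + np.array([dx, dy]),
            area=self.area, perimeter=self.perimeter,
            circularity=self.circularity,
            centroid=(self.centroid[0] + dx, self.centroid[1] + dy),
            bbox=Rect(self.bbox.x0 + dx, self.bbox.y0 + dy,
                      self.bbox.width, self.bbox.height))


@dataclass
class ParticleConfig:
    """Analysis-tab settings: size/shape filters and the ROI offset.

    ``roi_offset`` is added on each side of the spot's nominal bounding box
    when building the search region; the default of 20 px corresponds to
    twice the default blob diameter.
    """

    min_area: float = 1.0
    max_area: float = math.inf
    min_circularity: float = 0.0
    max_circularity: float = 1.0
    roi_offset: int = 20
    color_mode: str = "center"  # or "mean" over the particle

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_circularity <= self.max_circularity <= 1.0):
            raise ConfigError("need 0 <= min_circularity <= max_circularity <= 1")
        if self.min_area > self.max_area:
            raise ConfigError("min_area must be <= max_area")
        if self.roi_offset < 0:
            raise ConfigError("roi_offset must be >= 0")
        if self.color_mode not in ("center", "mean"):
            raise ConfigError("color_mode must be 'center' or 'mean'")


@dataclass
class FrameMeasurement:
    """Measurement of one track in one frame.

    ``status`` is 'measured', 'missing' (no acceptable particle in the ROI)
    or 'boundary_touch' (particle found but touching the ROI border — its
    area/color are still recorded, flagged as unreliable). ``center`` is the
    tracked (x, y) used to anchor the ROI; for gap frames it is linearly
    interpolated between the flanking detections.
    """

    track_id: int
    frame_index: int
    status: str
    roi: Rect
    center: tuple[float, float]
    area: int | None = None
    rgb: tuple[int, int, int] | None = None
    particle: Particle | None = field(default=None, repr=False)


class TrackMeasurements:
    """Per-(track, frame) measurement table; the export/diagnostics substrate."""

    def __init__(self, cells: Iterable[FrameMeasurement] = ()) -> None:
        self._cells: dict[tuple[int, int], FrameMeasurement] = {}
        for c in cells:
            self.put(c)

    def put(self, cell: FrameMeasurement) -> None:
        self._cells[(cell.track_id, cell.frame_index)] = cell

    def get(self, track_id: int, frame_index: int) -> FrameMeasurement:
        try:
            return self._cells[(track_id, frame_index)]
        except KeyError:
            raise LookupError_(f"no measurement for track {track_id} "
                               f"frame {frame_index}") from None

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self._cells

    def __len__(self) -> int:
        return len(self._cells)

    def __iter__(self):
        return iter(sorted(self._cells.values(),
                           key=lambda c: (c.track_id, c.frame_index)))

    @property
    def track_ids(self) -> list[int]:
        return sorted({tid for tid, _ in self._cells})

    @property
    def max_frame(self) -> int:
        return max((f for _, f in self._cells), default=-1)

    def drop_track(self, track_id: int) -> None:
        keys = [k for k in self._cells if k[0] == track_id]
        if not keys:
            raise LookupError_(f"unknown track id {track_id}")
        for k in keys:
            del self._cells[k]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self:
            r, g, b = c.rgb if c.rgb is not None else (None, None, None)
            rows.append({"track_id": c.track_id, "frame": c.frame_index,
                         "status": c.status, "area": c.area,
                         "R": r, "G": g, "B": b})
        return pd.DataFrame(rows, columns=["track_id", "frame", "status",
                                           "area", "R", "G", "B"])


def make_search_region(x: float, y: float, radius: float, roi_offset: int,
                       frame_width: int, frame_height: int) -> Rect:
    """Square ROI centered on the rounded spot center.

    Half-width = round(radius) + roi_offset, clamped to the frame.
    """
    cx, cy = int(round(x)), int(round(y))
    half = int(round(radius)) + int(roi_offset)
    return Rect(cx - half, cy - half, 2 * half + 1,
                2 * half + 1).clamped(frame_width, frame_height)


def crack_perimeter(mask: np.ndarray) -> int:
    """Exposed pixel-edge count of a boolean mask (all components pooled)."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1)
    per = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neigh = np.roll(padded, shift, axis=axis)
        per += int((padded & ~neigh).sum())
    return per


def analyze_particles(mask: np.ndarray,
                      config: ParticleConfig | None = None) -> list[Particle]:
    """Label 8-connected particles in a boolean mask and measure them.

    Particles failing the area/circularity filters are dropped; the result
    is ordered by decreasing area, then (y, x) of the centroid.
    """
    config = config or ParticleConfig()
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_STRUCTURE_8)
    particles: list[Particle] = []
    for obj_slice, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        sub = labels[obj_slice] == lab
        ys, xs = np.nonzero(sub)
        y_off, x_off = obj_slice[0].start, obj_slice[1].start
        xs = xs + x_off
        ys = ys + y_off
        area = int(sub.sum())
        perimeter = crack_perimeter(sub)
        circ = min(1.0, 4.0 * math.pi * area / perimeter ** 2)
        bbox = Rect(x_off, y_off,
                    int(xs.max()) - x_off + 1, int(ys.max()) - y_off + 1)
        if not (config.min_area <= area <= config.max_area):
            continue
        if not (config.min_circularity <= circ <= config.max_circularity):
            continue
        particles.append(Particle(
            pixels=np.column_stack([xs, ys]),
            area=area, perimeter=perimeter, circularity=circ,
            centroid=(float(xs.mean()), float(ys.mean())), bbox=bbox))
    particles.sort(key=lambda p: (-p.area, p.centroid[1], p.centroid[0]))
    return particles


def track_center(track: Track, frame_index: int) -> tuple[float, float, float]:
    """Tracked (x, y, radius) at a frame; linear interpolation inside gaps."""
    d = track.detections.get(frame_index)
    if d is not None:
        return d.x, d.y, d.radius
    frames = track.frames
    if not frames or not frames[0] <= frame_index <= frames[-1]:
        raise LookupError_(f"track {track.track_id} has no presence at "
                           f"frame {frame_index}")
    before = max(f for f in frames if f < frame_index)
    after = min(f for f in frames if f > frame_index)
    da, db = track.detections[before], track.detections[after]
    t = (frame_index - before) / (after - before)
    return (da.x + t * (db.x - da.x), da.y + t * (db.y - da.y),
            da.radius + t * (db.radius - da.radius))


def _select_particle(particles: Sequence[Particle], cx: int, cy: int
                     ) -> Particle | None:
    """Containment first, then nearest centroid (ties: larger area)."""
    if not particles:
        return None
    for p in particles:
        if p.contains(cx, cy):
            return p
    return min(particles,
               key=lambda p: ((p.centroid[0] - cx) ** 2
                              + (p.centroid[1] - cy) ** 2,
                              -p.area, p.centroid[1], p.centroid[0]))


def measure_region(track_id: int, frame_index: int, center: tuple[float, float],
                   region: Rect, binary_frame: np.ndarray,
                   color_frame: np.ndarray,
                   config: ParticleConfig) -> FrameMeasurement:
    """Particle analysis restricted to ``region``; shared by measurement
    and ROI-update repair."""
    region = region.clamped(binary_frame.shape[1], binary_frame.shape[0])
    sub = binary_frame[region.y0:region.y1, region.x0:region.x1]
    particles = [p.shifted(region.x0, region.y0)
                 for p in analyze_particles(sub, config)]
    cx, cy = int(round(center[0])), int(round(center[1]))
    chosen = _select_particle(particles, cx, cy)
    if chosen is None:
        return FrameMeasurement(track_id, frame_index, STATUS_MISSING,
                                roi=region, center=center)
    touches = (chosen.bbox.x0 == region.x0 or chosen.bbox.y0 == region.y0
               or chosen.bbox.x1 == region.x1 or chosen.bbox.y1 == region.y1)
    status = STATUS_BOUNDARY if touches else STATUS_MEASURED
    if config.color_mode == "mean" and chosen.area > 0:
        px = chosen.pixels
        rgb_arr = color_frame[px[:, 1], px[:, 0]].reshape(-1, 3)
        rgb = tuple(int(round(v)) for v in rgb_arr.mean(axis=0))
    else:
        yy = min(max(cy, 0), color_frame.shape[0] - 1)
        xx = min(max(cx, 0), color_frame.shape[1] - 1)
        rgb = tuple(int(v) for v in np.atleast_1d(color_frame[yy, xx])[:3])
    return FrameMeasurement(track_id, frame_index, status, roi=region,
                            center=center, area=chosen.area, rgb=rgb,
                            particle=chosen)


def measure_track_frame(track: Track, frame_index: int,
                        binary_frame: np.ndarray, color_frame: np.ndarray,
                        config: ParticleConfig | None = None
                        ) -> FrameMeasurement:
    """Measure one track in one frame (detection or interpolated gap center)."""
    config = config or ParticleConfig()
    x, y, radius = track_center(track, frame_index)
    region = make_search_region(x, y, radius, config.roi_offset,
                                binary_frame.shape[1], binary_frame.shape[0])
    return measure_region(track.track_id, frame_index, (x, y), region,
                          binary_frame, color_frame, config)


def measure_all(tracks: Sequence[Track], binary_stack: np.ndarray,
                color_stack: np.ndarray,
                config: ParticleConfig | None = None) -> TrackMeasurements:
    """One FrameMeasurement per (track, frame) over each track's life span.

    ``binary_stack`` is (n, H, W) boolean; ``color_stack`` is (n, H, W, 3).
    Gap frames are measured from interpolated centers so every track row is
    complete from its first to its last frame.
    """
    config = config or ParticleConfig()
    if binary_stack.shape[0] != color_stack.shape[0]:
        raise ConfigError("binary and color stacks must have equal frame counts")
    out = TrackMeasurements()
    for t in tracks:
        for f in range(t.first_frame, t.last_frame + 1):
            out.put(measure_track_frame(t, f, binary_stack[f],
                                        color_stack[f], config))
    return out
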