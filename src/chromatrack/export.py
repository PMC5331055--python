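"""Measurement tables (xlsx/CSV) and annotated overlay rendering.

The two output tables follow the classic layout: one row per track, one
column per frame (labeled ``Frame 1..N``, 1-based), the first table holding
surface areas in px² and the second the spot RGB color. Cells without a
clean measurement are left empty — an empty cell means "not measured",
never "zero area".
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .errors import ConfigError, InputError
from .particles import STATUS_MEASURED, TrackMeasurements
from .tracking import Track
from .video_io import VideoStack, write_video

__all__ = ["area_table", "color_table", "export_tables", "render_overlay"]

OVERLAY_COLOR = (255, 0, 255)     # magenta outlines, like the classic ROI color
ROI_COLOR = (0, 128, 255)         # unmeasured cells: search-region rectangle


def _frame_columns(n_frames: int) -> list[str]:
    return [f"Frame {i}" for i in range(1, n_frames + 1)]


def _n_frames(measurements: TrackMeasurements, n_frames: int | None) -> int:
    return n_frames if n_frames is not None else measurements.max_frame + 1


def area_table(measurements: TrackMeasurements,
               n_frames: int | None = None) -> pd.DataFrame:
    """Tracks x frames table of surface areas (px²); empty where unmeasured."""
    n = _n_frames(measurements, n_frames)
    cols = _frame_columns(n)
    df = pd.DataFrame(index=pd.Index(measurements.track_ids, name="track_id"),
                      columns=cols, dtype=object)
    for c in measurements:
        if c.status == STATUS_MEASURED and c.frame_index < n:
            df.at[c.track_id, cols[c.frame_index]] = int(c.area)
    return df


def color_table(measurements: TrackMeasurements, n_frames: int | None = None,
                split_rgb: bool = False) -> pd.DataFrame:
    """Tracks x frames table of spot colors.

    Packed as one ``"R,G,B"`` text cell per frame, or three numeric columns
    per frame (``Frame k R/G/B``) when ``split_rgb`` is set.
    """
    n = _n_frames(measurements, n_frames)
    idx = pd.Index(measurements.track_ids, name="track_id")
    if split_rgb:
        cols = [f"Frame {i} {ch}" for i in range(1, n + 1) for ch in "RGB"]
        df = pd.DataFrame(index=idx, columns=cols, dtype=object)
        for c in measurements:
            if c.status == STATUS_MEASURED and c.frame_index < n:
                for ch, v in zip("RGB", c.rgb):
                    df.at[c.track_id, f"Frame {c.frame_index + 1} {ch}"] = int(v)
    else:
        cols = _frame_columns(n)
        df = pd.DataFrame(index=idx, columns=cols, dtype=object)
        for c in measurements:
            if c.status == STATUS_MEASURED and c.frame_index < n:
                df.at[c.track_id, cols[c.frame_index]] = (
                    f"{c.rgb[0]},{c.rgb[1]},{c.rgb[2]}")
    return df


def export_tables(measurements: TrackMeasurements, path: str | Path,
                  format: str = "xlsx", n_frames: int | None = None,
                  split_rgb: bool = False) -> list[Path]:
    """Write the Area and Color tables.

    ``format='xlsx'`` writes one workbook with sheets "Area" and "Color";
    ``format='csv'`` writes ``<stem>_area.csv`` and ``<stem>_color.csv``.
    Measured values round-trip exactly. Returns the written paths.
    """
    path = Path(path)
    areas = area_table(measurements, n_frames)
    colors = color_table(measurements, n_frames, split_rgb=split_rgb)
    if format == "xlsx":
        out = path if path.suffix == ".xlsx" else path.with_suffix(".xlsx")
        try:
            with pd.ExcelWriter(out, engine="openpyxl") as xl:
                areas.to_excel(xl, sheet_name="Area")
                colors.to_excel(xl, sheet_name="Color")
        except OSError as e:
            raise InputError(f"cannot write {out}: {e}") from e
        return [out]
    if format == "csv":
        stem = path.with_suffix("")
        out_a = stem.parent / f"{stem.name}_area.csv"
        out_c = stem.parent / f"{stem.name}_color.csv"
        try:
            areas.to_csv(out_a)
            colors.to_csv(out_c)
        except OSError as e:
            raise InputError(f"cannot write {path}: {e}") from e
        return [out_a, out_c]
    raise ConfigError(f"unknown export format {format!r} (use xlsx or csv)")


def _outline_pixels(pixels: np.ndarray) -> np.ndarray:
    """Subset of particle pixels with at least one 4-neighbor outside it."""
    xs, ys = pixels[:, 0], pixels[:, 1]
    x0, y0 = xs.min(), ys.min()
    sub = np.zeros((ys.max() - y0 + 3, xs.max() - x0 + 3), dtype=bool)
    sub[ys - y0 + 1, xs - x0 + 1] = True
    interior = (sub & np.roll(sub, 1, 0) & np.roll(sub, -1, 0)
                & np.roll(sub, 1, 1) & np.roll(sub, -1, 1))
    edge = sub & ~interior
    ey, ex = np.nonzero(edge)
    return np.column_stack([ex + x0 - 1, ey + y0 - 1])


def render_overlay(stack: VideoStack, tracks: Sequence[Track],
                   measurements: TrackMeasurements, out_path: str | Path,
                   outline_color: tuple[int, int, int] = OVERLAY_COLOR,
                   roi_color: tuple[int, int, int] = ROI_COLOR,
                   draw_labels: bool = True) -> Path:
    """Render the review video: particle outlines plus "id: area" labels.

    Measured (and boundary-flagged) cells draw the particle's 1-px contour;
    cells without a particle draw their search region as a rectangle in a
    distinct color. Pixels outside drawn annotations are left untouched.
    ``out_path`` ending in ``.avi`` writes an uncompressed video, otherwise
    a PNG frame directory.
    """
    if not stack.is_color:
        raise ConfigError("overlay rendering expects the color stack")
    by_frame: dict[int, list] = {}
    for c in measurements:
        by_frame.setdefault(c.frame_index, []).append(c)
    if by_frame and max(by_frame) >= stack.n_frames:
        raise InputError("measurement frame indices exceed the video length")

    frames_out = stack.frames.copy()
    for f in range(stack.n_frames):
        cells = by_frame.get(f, [])
        if not cells:
            continue
        img = Image.fromarray(frames_out[f])
        draw = ImageDraw.Draw(img)
        arr = None
        for c in cells:
            if c.particle is not None:
                outline = _outline_pixels(c.particle.pixels)
                if arr is None:
                    arr = np.asarray(img).copy()
                inb = ((outline[:, 0] >= 0) & (outline[:, 0] < stack.width)
                       & (outline[:, 1] >= 0) & (outline[:, 1] < stack.height))
                outline = outline[inb]
                arr[outline[:, 1], outline[:, 0]] = outline_color
                img = Image.fromarray(arr)
                draw = ImageDraw.Draw(img)
                if draw_labels:
                    bx = c.particle.bbox
                    draw.text((bx.x0, max(0, bx.y0 - 10)),
                              f"{c.track_id}: {c.area}", fill=outline_color)
                arr = np.asarray(img).copy()
            else:
                r = c.roi
                draw.rectangle([r.x0, r.y0, r.x1 - 1, r.y1 - 1],
                               outline=roi_color)
                arr = np.asarray(img).copy()
        frames_out[f] = np.asarray(img)
    return Path(write_video(VideoStack(frames_out, fps=stack.fps), out_path))
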