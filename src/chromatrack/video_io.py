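"""Video and image-stack I/O plus basic raster geometry.

Frames are numpy arrays: grayscale ``(H, W)`` or color ``(H, W, 3)``, dtype
``uint8``. Coordinates are 0-based with ``x`` = column and ``y`` = row; pixel
centers sit at integer coordinates. Supported containers are numbered
PNG/TIFF frame directories and uncompressed 24-bit RGB AVI files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, InputError
from ._avi import read_avi, write_avi

__all__ = ["Rect", "VideoStack", "read_video", "write_frames", "write_video",
           "to_grayscale", "crop"]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle: ``x0/y0`` inclusive top-left corner."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"Rect must have positive size, got {self}")

    @property
    def x1(self) -> int:
        """Exclusive right edge."""
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        """Exclusive bottom edge."""
        return self.y0 + self.height

    def clamped(self, frame_width: int, frame_height: int) -> "Rect":
        """Intersection with the frame; raises if the overlap is empty."""
        x0 = max(self.x0, 0)
        y0 = max(self.y0, 0)
        x1 = min(self.x1, frame_width)
        y1 = min(self.y1, frame_height)
        if x1 <= x0 or y1 <= y0:
            raise InputError(f"{self} lies fully outside a "
                             f"{frame_width}x{frame_height} frame")
        return Rect(x0, y0, x1 - x0, y1 - y0)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass
class VideoStack:
    """An ordered stack of equally sized frames.

    ``frames`` has shape ``(n_frames, H, W)`` for 8-bit grayscale or
    ``(n_frames, H, W, 3)`` for color, dtype uint8. ``fps`` is carried as
    metadata only; all measurements in this package are per frame.
    """

    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise FormatError(f"expected (n,H,W[,3]) frame array, "
                              f"got shape {self.frames.shape}")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise FormatError("color frames must have exactly 3 channels")
        if self.frames.shape[0] < 1:
            raise InputError("a VideoStack needs at least one frame")
        if self.frames.dtype != np.uint8:
            raise FormatError(f"frames must be uint8, got {self.frames.dtype}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def frame(self, index: int) -> np.ndarray:
        return self.frames[index]


def _numeric_key(path: Path) -> tuple:
    """Sort key: first run of digits in the stem, then the name itself."""
    m = re.search(r"\d+", path.stem)
    return (int(m.group()) if m else -1, path.name)


def read_video(path: str | Path, fps_override: float | None = None) -> VideoStack:
    """Read an AVI file or a numbered PNG/TIFF frame directory.

    Returns a color stack preserving frame order. Grayscale sources are
    promoted to 3 identical channels so downstream color measurement always
    has an RGB frame to sample.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input path does not exist: {path}")
    if path.is_dir():
        files = sorted((p for p in path.iterdir()
                        if p.suffix.lower() in _FRAME_SUFFIXES), key=_numeric_key)
        if not files:
            raise InputError(f"no PNG/TIFF frames found in directory {path}")
        frames = []
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3 and img.shape[-1] == 4:  # drop alpha
                img = img[..., :3]
            frames.append(img)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FormatError(f"frames in {path} have unequal sizes: {shapes}")
        arr = np.stack(frames).astype(np.uint8)
        fps = fps_override if fps_override is not None else 30.0
        stack = VideoStack(arr, fps=fps)
    elif path.suffix.lower() == ".avi":
        frames, fps = read_avi(path)
        if fps_override is not None:
            fps = fps_override
        stack = VideoStack(frames, fps=fps)
    else:
        raise InputError(f"unsupported input {path}: expected an .avi file or "
                         f"a directory of numbered PNG/TIFF frames")
    if not stack.is_color:
        stack = VideoStack(np.repeat(stack.frames[..., None], 3, axis=-1),
                           fps=stack.fps)
    return stack


def write_frames(stack: VideoStack, directory: str | Path,
                 fmt: str = "png") -> list[Path]:
    """Write every frame as ``frame_0000.<fmt>`` files; returns the paths."""
    if fmt not in ("png", "tif", "tiff"):
        raise InputError(f"unsupported frame format: {fmt}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(stack.n_frames):
        p = directory / f"frame_{i:04d}.{fmt}"
        iio.imwrite(p, stack.frame(i))
        paths.append(p)
    return paths


def write_video(stack: VideoStack, path: str | Path) -> Path:
    """Write the stack as an uncompressed RGB AVI (or frames if a directory)."""
    path = Path(path)
    if path.suffix.lower() == ".avi":
        frames = stack.frames
        if not stack.is_color:
            frames = np.repeat(frames[..., None], 3, axis=-1)
        write_avi(path, frames, fps=stack.fps)
        return path
    write_frames(stack, path)
    return path


def to_grayscale(stack: VideoStack) -> VideoStack:
    """8-bit grayscale via the unweighted channel mean.

    Each pixel becomes ``floor((R+G+B)/3 + 0.5)`` — the plain mean with
    round-half-up, matching the classic ImageJ 8-bit conversion rather than
    ITU luma weighting. Grayscale input is returned unchanged.
    """
    if not stack.is_color:
        return stack
    s = stack.frames.astype(np.uint32).sum(axis=-1)
    gray = ((2 * s + 3) // 6).astype(np.uint8)  # floor(s/3 + 1/2), exact
    return VideoStack(gray, fps=stack.fps)


def crop(stack: VideoStack, region: Rect) -> VideoStack:
    """Crop every frame to ``region`` clamped to the frame bounds."""
    r = region.clamped(stack.width, stack.height)
    return VideoStack(stack.frames[:, r.y0:r.y1, r.x0:r.x1].copy(),
                      fps=stack.fps)
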