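"""Synthetic chromatophore-like videos with exact ground truth.

Scenes emulate what pigment-organ footage looks like to this pipeline: dark
round spots on a lighter background whose radii expand or retract over time,
with optional per-frame jitter or drift, Gaussian blur, additive Gaussian
noise, and scripted occlusions (frames in which a spot is simply not drawn)
for exercising gap closing.

Spots are drawn as hard (non-anti-aliased) disks — a pixel belongs to a spot
iff ``(px - x)² + (py - y)² <= r²`` at the pixel center — so the true area
is an exact integer pixel count, shared by :func:`truth_area`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ConfigError, SpotOccludedError
from .video_io import VideoStack

__all__ = ["SceneConfig", "SpotTruth", "GroundTruth", "generate_video",
           "truth_area", "rasterized_disk_area"]

RADIUS_DYNAMICS = ("constant", "sigmoid_expand", "sigmoid_retract", "pulse")
MOTIONS = ("static", "jitter", "drift")


@dataclass
class SceneConfig:
    """Scene parameters; every random choice derives from ``seed``.

    Defaults describe a benign benchmark scene: 20 well-separated static
    dark disks of radius 5 on a light gray background, noiseless, 50 frames
    of a 128x128 view.
    """

    width: int = 128
    height: int = 128
    n_frames: int = 50
    n_spots: int = 20
    background_rgb: tuple[int, int, int] = (220, 220, 220)
    radius_dynamics: str = "constant"
    r_min: float = 2.0
    r_max: float = 5.0
    onset_frame: float = 10.0
    rate: float = 0.3          # logistic growth rate, 1/frames
    pulse_width: float = 20.0  # frames between expansion and retraction
    motion: str = "static"
    jitter_sigma: float = 0.0  # px/frame, for motion="jitter"
    drift: tuple[float, float] = (0.0, 0.0)  # px/frame, for motion="drift"
    noise_sigma: float = 0.0   # gray levels
    blur_sigma: float = 0.0    # px
    occlusions: list[tuple[int, int, int]] = field(default_factory=list)
    # each: (spot_id, start_frame, length)
    seed: int = 0
    centers: list[tuple[float, float]] | None = None  # overrides placement
    colors: list[tuple[int, int, int]] | None = None
    allow_overlap: bool = False
    margin: float = 2.0        # extra frame-edge clearance, px

    def __post_init__(self) -> None:
        if self.radius_dynamics not in RADIUS_DYNAMICS:
            raise ConfigError(f"unknown radius_dynamics {self.radius_dynamics!r}")
        if self.motion not in MOTIONS:
            raise ConfigError(f"unknown motion {self.motion!r}")
        if self.n_frames < 1 or self.n_spots < 0:
            raise ConfigError("need n_frames >= 1 and n_spots >= 0")
        if self.r_max < self.r_min or self.r_min < 0:
            raise ConfigError("need 0 <= r_min <= r_max")


@dataclass
class SpotTruth:
    """Ground truth for one spot: trajectory, radius series, color, occlusions."""

    spot_id: int
    color: tuple[int, int, int]
    centers: np.ndarray   # (n_frames, 2) float, columns (x, y)
    radii: np.ndarray     # (n_frames,) float
    occluded: set[int] = field(default_factory=set)

    def drawn(self, frame: int) -> bool:
        return frame not in self.occluded


@dataclass
class GroundTruth:
    """All spot truths for one generated scene."""

    spots: list[SpotTruth]
    config: SceneConfig

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def spot(self, spot_id: int) -> SpotTruth:
        for s in self.spots:
            if s.spot_id == spot_id:
                return s
        raise KeyError(f"unknown spot id {spot_id}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.spots:
            for f in range(self.config.n_frames):
                rows.append({
                    "spot_id": s.spot_id, "frame": f,
                    "x": s.centers[f, 0], "y": s.centers[f, 1],
                    "r": s.radii[f], "R": s.color[0], "G": s.color[1],
                    "B": s.color[2], "occluded": int(f in s.occluded)})
        return pd.DataFrame(rows)


def rasterized_disk_area(x: float, y: float, r: float) -> int:
    """Exact pixel count of the hard disk: pixels with (px-x)²+(py-y)² <= r²."""
    if r < 0:
        return 0
    x0, x1 = math.floor(x - r), math.ceil(x + r)
    y0, y1 = math.floor(y - r), math.ceil(y + r)
    px, py = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    return int(((px - x) ** 2 + (py - y) ** 2 <= r * r).sum())


def truth_area(ground_truth: GroundTruth, spot_id: int, frame: int) -> int:
    """True drawn area (px²) of a spot at a frame, by exact rasterization."""
    s = ground_truth.spot(spot_id)
    if frame in s.occluded:
        raise SpotOccludedError(f"spot {spot_id} is occluded at frame {frame}")
    x, y = s.centers[frame]
    return rasterized_disk_area(float(x), float(y), float(s.radii[frame]))


def _radius_series(cfg: SceneConfig, n: int) -> np.ndarray:
    t = np.arange(n, dtype=np.float64)
    lo, hi, k, t0 = cfg.r_min, cfg.r_max, cfg.rate, cfg.onset_frame

    def sig(shift: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-k * (t - shift)))

    if cfg.radius_dynamics == "constant":
        return np.full(n, hi)
    if cfg.radius_dynamics == "sigmoid_expand":
        return lo + (hi - lo) * sig(t0)
    if cfg.radius_dynamics == "sigmoid_retract":
        return hi - (hi - lo) * sig(t0)
    # pulse: expand at onset, retract pulse_width frames later
    return lo + (hi - lo) * (sig(t0) - sig(t0 + cfg.pulse_width))


def _place_centers(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    lo_x = cfg.r_max + cfg.margin
    hi_x = cfg.width - 1 - cfg.r_max - cfg.margin
    lo_y = cfg.r_max + cfg.margin
    hi_y = cfg.height - 1 - cfg.r_max - cfg.margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ConfigError("frame too small for spots of this radius")
    min_sep = 2 * cfg.r_max + 4
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < cfg.n_spots:
        attempts += 1
        if attempts > 20000:
            raise ConfigError(
                f"could not place {cfg.n_spots} spots with pairwise "
                f"separation >= {min_sep:.1f}px in a "
                f"{cfg.width}x{cfg.height} frame")
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if cfg.allow_overlap or all(
                (x - cx) ** 2 + (y - cy) ** 2 >= min_sep ** 2
                for cx, cy in centers):
            centers.append((x, y))
    return np.array(centers, dtype=np.float64).reshape(cfg.n_spots, 2)


def generate_video(config: SceneConfig) -> tuple[VideoStack, GroundTruth]:
    """Render the scene; same config (incl. seed) gives bit-identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, h, w = cfg.n_frames, cfg.height, cfg.width

    if cfg.centers is not None:
        if len(cfg.centers) != cfg.n_spots:
            raise ConfigError("len(centers) must equal n_spots")
        base = np.array(cfg.centers, dtype=np.float64).reshape(cfg.n_spots, 2)
    else:
        base = _place_centers(cfg, rng)

    if cfg.colors is not None:
        if len(cfg.colors) != cfg.n_spots:
            raise ConfigError("len(colors) must equal n_spots")
        colors = [tuple(int(v) for v in c) for c in cfg.colors]
    else:
        colors = [tuple(int(v) for v in rng.integers(10, 140, size=3))
                  for _ in range(cfg.n_spots)]

    radii = _radius_series(cfg, n)
    occluded_by_spot: dict[int, set[int]] = {i + 1: set()
                                             for i in range(cfg.n_spots)}
    for spot_id, start, length in cfg.occlusions:
        if spot_id not in occluded_by_spot:
            raise ConfigError(f"occlusion names unknown spot id {spot_id}")
        occluded_by_spot[spot_id].update(range(start, start + length))

    # Per-frame centers: static, Gaussian jitter, or constant drift. Centers
    # are clamped so spots stay fully inside the frame.
    centers = np.empty((cfg.n_spots, n, 2), dtype=np.float64)
    centers[:, 0, :] = base
    for f in range(1, n):
        if cfg.motion == "static":
            step = 0.0
        elif cfg.motion == "drift":
            step = np.array(cfg.drift, dtype=np.float64)
        else:
            step = rng.normal(0.0, cfg.jitter_sigma, size=(cfg.n_spots, 2))
        centers[:, f, :] = centers[:, f - 1, :] + step
    centers[..., 0] = np.clip(centers[..., 0], cfg.r_max + cfg.margin,
                              w - 1 - cfg.r_max - cfg.margin)
    centers[..., 1] = np.clip(centers[..., 1], cfg.r_max + cfg.margin,
                              h - 1 - cfg.r_max - cfg.margin)

    spots = [SpotTruth(spot_id=i + 1, color=colors[i],
                       centers=centers[i], radii=radii.copy(),
                       occluded=occluded_by_spot[i + 1])
             for i in range(cfg.n_spots)]

    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    for f in range(n):
        img = np.empty((h, w, 3), dtype=np.float64)
        img[:] = cfg.background_rgb
        for s in spots:
            if f in s.occluded:
                continue
            x, y = s.centers[f]
            r = s.radii[f]
            mask = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
            img[mask] = s.color
        if cfg.blur_sigma > 0:
            for c in range(3):
                img[..., c] = ndi.gaussian_filter(img[..., c], cfg.blur_sigma)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return VideoStack(frames), GroundTruth(spots=spots, config=cfg)
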