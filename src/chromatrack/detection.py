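"""Per-frame blob detection.

Spots are found as local maxima of a negated Laplacian-of-Gaussian (LoG)
response at a single scale tied to the nominal blob diameter. The input
frame must be polarity-normalized so spots are bright (the pipeline inverts
light-background footage before detection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import ConfigError

__all__ = ["SpotDetection", "DetectionConfig", "log_response", "detect_spots",
           "filter_detections"]


@dataclass(frozen=True)
class SpotDetection:
    """One candidate spot in one frame.

    ``quality`` is the (scale-normalized) LoG peak response; larger means a
    stronger, better-contrasted blob at the configured diameter.
    """

    frame_index: int
    x: float
    y: float
    radius: float
    quality: float


@dataclass
class DetectionConfig:
    """Tracking-tab detector settings.

    blob_diameter : nominal spot diameter in px (default 10); spots much
        smaller than this produce weak responses and are effectively ignored.
    quality_threshold : minimum LoG peak response (default 0 keeps every
        positive peak).
    min_separation : minimum center distance between detections; defaults to
        blob_diameter / 2.
    min_radius : optional radius floor, a second reading of the GUI's
        "blob threshold" as a size cutoff; None disables it.
    """

    blob_diameter: float = 10.0
    quality_threshold: float = 0.0
    min_separation: float | None = None
    min_radius: float | None = None

    def __post_init__(self) -> None:
        if self.blob_diameter <= 0:
            raise ConfigError("blob_diameter must be > 0")
        if self.quality_threshold < 0:
            raise ConfigError("quality_threshold must be >= 0")
        if self.min_separation is None:
            self.min_separation = self.blob_diameter / 2.0

    @property
    def sigma(self) -> float:
        """LoG scale at which a disk of blob_diameter maximizes response."""
        return self.blob_diameter / (2.0 * math.sqrt(2.0))


def log_response(frame: np.ndarray, blob_diameter: float) -> np.ndarray:
    """Scale-normalized negated LoG response; bright blobs give positive peaks."""
    sigma = blob_diameter / (2.0 * math.sqrt(2.0))
    resp = -ndi.gaussian_laplace(np.asarray(frame, dtype=np.float64), sigma,
                                 mode="reflect")
    return resp * sigma * sigma


def detect_spots(frame: np.ndarray, config: DetectionConfig,
                 frame_index: int = 0) -> list[SpotDetection]:
    """Detect blobs of the configured diameter in one grayscale frame.

    Local maxima of the LoG response with response strictly above the quality
    threshold are kept; maxima closer than ``min_separation`` are suppressed
    keeping the stronger one (ties broken toward smaller (y, x)). Detections
    are returned sorted by (y, x).
    """
    resp = log_response(frame, config.blob_diameter)
    local_max = resp >= ndi.maximum_filter(resp, size=3, mode="reflect")
    candidates = local_max & (resp > config.quality_threshold)
    ys, xs = np.nonzero(candidates)
    if ys.size == 0:
        return []
    qual = resp[ys, xs]
    order = np.lexsort((xs, ys, -qual))  # strongest first, then (y, x)
    pts = np.column_stack([ys[order], xs[order]]).astype(np.float64)
    quals = qual[order]
    min_sep = float(config.min_separation)
    min_sep_sq = min_sep * min_sep
    tree = cKDTree(pts)
    alive = np.ones(len(pts), dtype=bool)
    for i in range(len(pts)):
        if not alive[i]:
            continue  # only surviving maxima suppress weaker neighbors
        for j in tree.query_ball_point(pts[i], min_sep):
            if j > i and alive[j]:
                d2 = (pts[i, 0] - pts[j, 0]) ** 2 + (pts[i, 1] - pts[j, 1]) ** 2
                if d2 < min_sep_sq:
                    alive[j] = False
    radius = config.blob_diameter / 2.0
    dets = [SpotDetection(frame_index, float(p[1]), float(p[0]), radius,
                          float(q))
            for p, q, a in zip(pts, quals, alive) if a]
    if config.min_radius is not None:
        dets = [d for d in dets if d.radius >= config.min_radius]
    dets.sort(key=lambda d: (d.y, d.x))
    return dets


def filter_detections(detections: list[SpotDetection],
                      quality_threshold: float) -> list[SpotDetection]:
    """Keep detections with quality >= threshold, preserving order."""
    return [d for d in detections if d.quality >= quality_threshold]
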