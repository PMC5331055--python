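"""Background subtraction and automatic thresholding.

Turns raw 8-bit grayscale frames into spot-foreground images: a smooth
background estimate (grayscale morphological opening with a disk) is removed,
then an iterative-intermeans (IsoData-family) threshold separates spot pixels
from background, frame by frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigError

__all__ = ["PreprocessConfig", "ThresholdResult", "subtract_background",
           "auto_threshold", "disk_footprint", "preprocess_frame"]

THRESHOLD_METHODS = ("default",)


@dataclass
class PreprocessConfig:
    """Processing-tab settings.

    subtract_background_radius : disk radius in px for the background
        estimate; 0 disables subtraction. Default 50.
    dark_background : False means spots are dark on a light background
        (the usual appearance of pigmented chromatophores on pale skin).
    """

    subtract_background_radius: int = 50
    dark_background: bool = False
    threshold_method: str = "default"
    apply_threshold: bool = True

    def __post_init__(self) -> None:
        if self.subtract_background_radius < 0:
            raise ConfigError("subtract_background_radius must be >= 0")
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ConfigError(
                f"unknown threshold method {self.threshold_method!r}; "
                f"available: {THRESHOLD_METHODS}")


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk: pixel included iff dx² + dy² <= radius²."""
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return (dx * dx + dy * dy) <= r * r


def _disk_halfwidths(radius: int) -> np.ndarray:
    dy = np.arange(-radius, radius + 1)
    return np.floor(np.sqrt(radius * radius - dy * dy + 0.0)).astype(int)


def _disk_filter(frame: np.ndarray, radius: int, minimum: bool) -> np.ndarray:
    """Exact min/max filter over a disk footprint.

    Decomposes the disk into its horizontal runs: one 1-D running min (max)
    per distinct run half-width, then a column-wise reduction over the
    vertical offsets. Out-of-frame pixels never influence the result
    (equivalent to constant padding with the filter's neutral element).
    """
    r = int(radius)
    cval = 255 if minimum else 0
    reduce_ = np.minimum if minimum else np.maximum
    filt1d = ndi.minimum_filter1d if minimum else ndi.maximum_filter1d
    h, w = frame.shape
    padded = np.full((h + 2 * r, w + 2 * r), cval, dtype=frame.dtype)
    padded[r:r + h, r:r + w] = frame
    halfwidths = _disk_halfwidths(r)
    row_filtered = {hw: filt1d(padded, 2 * hw + 1, axis=1, mode="nearest")
                    for hw in np.unique(halfwidths)}
    out = None
    for dy, hw in zip(range(-r, r + 1), halfwidths):
        sl = row_filtered[hw][r + dy:r + dy + h, r:r + w]
        out = sl.copy() if out is None else reduce_(out, sl, out=out)
    return out


def _opening(frame: np.ndarray, radius: int) -> np.ndarray:
    return _disk_filter(_disk_filter(frame, radius, minimum=True),
                        radius, minimum=False)


def subtract_background(frame: np.ndarray, radius: int,
                        light_background: bool = True) -> np.ndarray:
    """Remove a smooth background estimated by disk opening.

    The background is the grayscale morphological opening (erosion then
    dilation) with a disk structuring element of the given radius — the
    "rolling ball" idea with a flat ball. For light backgrounds the frame is
    inverted before and after, so the output keeps the input polarity
    (light background stays light). ``radius == 0`` disables subtraction.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ConfigError("subtract_background expects a 2-D grayscale frame")
    if radius == 0:
        return frame.copy()
    if radius >= min(frame.shape):
        warnings.warn(
            f"background radius {radius} >= smallest frame dimension "
            f"{min(frame.shape)}; background estimate may be degenerate",
            stacklevel=2)
    work = (255 - frame) if light_background else frame
    background = _opening(work, radius)
    residual = np.clip(work.astype(np.int16) - background, 0, 255)
    residual = residual.astype(np.uint8)
    return (255 - residual) if light_background else residual


@dataclass
class ThresholdResult:
    """Binary spot mask plus the gray level that produced it.

    ``mask`` is True on spot pixels regardless of image polarity.
    ``degenerate`` flags a constant frame, for which no threshold exists and
    the mask is empty.
    """

    mask: np.ndarray
    threshold: int
    degenerate: bool = False


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def intermeans_threshold(hist: np.ndarray) -> int:
    """Iterative intermeans threshold on a 256-bin histogram.

    Returns the smallest t satisfying the intermeans self-consistency
    condition ``t == round((mean of bins <= t) + (mean of bins > t)) / 2``,
    found by scanning upward from the darkest occupied bin — the classic
    "Default" behavior. Scanning from below matters: a histogram dominated
    by a bright background lump has further self-consistent points inside
    the lump, and only the lowest one separates a small dark spot class
    from the background. Candidates are clamped inside
    [first, last - 1] occupied bin so both classes stay populated; ties
    round half up. Raises ValueError when fewer than two bins are occupied.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    occupied = np.nonzero(hist)[0]
    if len(occupied) < 2:
        raise ValueError("histogram has fewer than two occupied bins")
    lo_bin, hi_bin = int(occupied[0]), int(occupied[-1])
    levels = np.arange(256, dtype=np.float64)
    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * levels)
    total_n, total_m = csum[-1], cmoment[-1]
    for t in range(lo_bin, hi_bin):
        m_low = cmoment[t] / csum[t]
        m_high = (total_m - cmoment[t]) / (total_n - csum[t])
        mapped = _round_half_up((m_low + m_high) / 2.0)
        if min(max(mapped, lo_bin), hi_bin - 1) == t:
            return t
    return hi_bin - 1  # monotone map: the top candidate is then fixed


def auto_threshold(frame: np.ndarray, method: str = "default",
                   dark_background: bool = False) -> ThresholdResult:
    """Per-frame automatic threshold ("Default" = iterative intermeans).

    With ``dark_background=False`` (light background) spots are the dark
    class: mask = pixels <= t. With ``dark_background=True`` spots are the
    bright class: mask = pixels > t. Either way the returned mask is True
    exactly on spot pixels.
    """
    if method not in THRESHOLD_METHODS:
        raise ConfigError(f"unknown threshold method {method!r}")
    frame = np.asarray(frame)
    if frame.min() == frame.max():  # constant frame: no threshold exists
        return ThresholdResult(np.zeros(frame.shape, dtype=bool),
                               threshold=int(frame.flat[0]), degenerate=True)
    hist = np.bincount(frame.ravel(), minlength=256)[:256]
    t = intermeans_threshold(hist)
    mask = (frame > t) if dark_background else (frame <= t)
    return ThresholdResult(mask=mask, threshold=t)


def preprocess_frame(frame: np.ndarray, config: PreprocessConfig
                     ) -> tuple[np.ndarray, ThresholdResult | None]:
    """Apply background subtraction then thresholding to one gray frame.

    Returns ``(subtracted, threshold_result)``; the threshold result is None
    when ``apply_threshold`` is off.
    """
    sub = subtract_background(frame, config.subtract_background_radius,
                              light_background=not config.dark_background)
    if not config.apply_threshold:
        return sub, None
    return sub, auto_threshold(sub, config.threshold_method,
                               config.dark_background)
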