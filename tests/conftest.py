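"""Shared fixtures and independent oracles.

The oracle helpers here deliberately re-derive quantities by brute force
(flood fill, exhaustive scans, explicit kernel convolution) so they share no
code path with the implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

import chromatrack as ct

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def noiseless_scene():
    """The benchmark scene: 20 static dark r=5 disks, 50 frames, 128x128."""
    cfg = ct.SceneConfig(seed=1)
    stack, truth = ct.generate_video(cfg)
    return stack, truth


@pytest.fixture(scope="session")
def noiseless_result(noiseless_scene):
    stack, _ = noiseless_scene
    return ct.run_pipeline(ct.RunConfig(), stack=stack)


def match_tracks_to_truth(tracks, truth):
    """Map track_id -> spot_id by nearest first-frame center."""
    mapping = {}
    for t in tracks:
        f = t.first_frame
        d = t.detections[f]
        best = min(truth.spots,
                   key=lambda s: (s.centers[f, 0] - d.x) ** 2
                   + (s.centers[f, 1] - d.y) ** 2)
        mapping[t.track_id] = best.spot_id
    return mapping


# ------------------------------------------------------------------ oracles

def flood_fill_components(mask):
    """8-connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack, pixels = [(sy, sx)], []
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                pixels.append((x, y))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            comps.append(frozenset(pixels))
    return comps


def crack_perimeter_oracle(pixels):
    """Count exposed pixel edges of a pixel set by direct enumeration."""
    pset = set(map(tuple, pixels))
    per = 0
    for (x, y) in pset:
        for nx, ny in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
            if (nx, ny) not in pset:
                per += 1
    return per


def disk_pixel_count_oracle(cx, cy, r):
    """Rasterized disk area by per-pixel loop with the inclusion rule."""
    count = 0
    for py in range(math.floor(cy - r) - 1, math.ceil(cy + r) + 2):
        for px in range(math.floor(cx - r) - 1, math.ceil(cx + r) + 2):
            if (px - cx) ** 2 + (py - cy) ** 2 <= r * r:
                count += 1
    return count


def intermeans_fixed_points(hist):
    """All self-consistent intermeans thresholds, by exhaustive scan.

    Mirrors the stated threshold definition (candidates clamped inside the
    occupied range so both classes are populated) but checks every
    candidate t directly instead of iterating.
    """
    hist = np.asarray(hist, dtype=float)
    occupied = np.nonzero(hist)[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    levels = np.arange(256.0)
    out = []
    for t in range(lo, hi):
        low, high = hist[: t + 1], hist[t + 1:]
        m_low = (low * levels[: t + 1]).sum() / low.sum()
        m_high = (high * levels[t + 1:]).sum() / high.sum()
        mapped = int(np.floor((m_low + m_high) / 2.0 + 0.5))
        if min(max(mapped, lo), hi - 1) == t:
            out.append(t)
    return out


def brute_force_assignment(src, dst, max_distance):
    """Best one-to-one matching by exhaustive enumeration (<= 6x6).

    Returns (cardinality, min total squared distance) over matchings that
    use only pairs within the distance cap, maximizing cardinality first.
    """
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    cap_sq = max_distance ** 2
    n, m = len(src), len(dst)
    best = (0, 0.0)
    idx_small, idx_big, swapped = ((range(n), range(m), False) if n <= m
                                   else (range(m), range(n), True))
    k = len(list(idx_small))
    for subset in itertools.permutations(list(idx_big), k):
        for keep in itertools.product([0, 1], repeat=k):
            card, cost, ok = 0, 0.0, True
            for i, j, used in zip(idx_small, subset, keep):
                if not used:
                    continue
                a, b = (i, j) if not swapped else (j, i)
                d2 = ((src[a] - dst[b]) ** 2).sum()
                if d2 > cap_sq:
                    ok = False
                    break
                card += 1
                cost += d2
            if ok and (card > best[0]
                       or (card == best[0] and cost < best[1])):
                best = (card, cost)
    return best
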