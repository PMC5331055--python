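# Methods

`chromatrack` measures the activity of round pigmented spots —
prototypically cephalopod chromatophore organs, whose radial muscles expand
and retract the pigment sac on sub-second time scales — from color video.
The pipeline mirrors the classic Fiji-based workflow: convert to 8-bit
grayscale, subtract a smooth background, auto-threshold every frame, detect
blobs, link them into tracks with gap closing, measure each track's
connected particle per frame (surface area in px², RGB color), diagnose and
repair incomplete tracks, and export two spreadsheet tables plus an
annotated overlay video. Every stage is deterministic; identical
configuration and input give byte-identical outputs.

## Preprocessing

**Grayscale.** Color frames are reduced with the unweighted channel mean,
`floor((R+G+B)/3 + 0.5)` — the classic ImageJ 8-bit conversion, not ITU
luma weights — because downstream thresholds were historically tuned to
that convention.

**Background subtraction** (`subtract_background_radius`, default 50 px; 0
disables). The background estimate is a grayscale morphological opening
(erosion then dilation) with a disk structuring element — the flat-ball
version of rolling-ball subtraction. For light backgrounds (the default:
pigmented spots are dark on pale skin) the frame is inverted before and
after, so output polarity matches input. The radius should comfortably
exceed the largest spot diameter; at the default 50 px any spot up to
~50 px across is fully removed from the estimate. Large-radius openings
are computed exactly by decomposing the disk into its horizontal chords:
one 1-D running min/max per distinct chord half-width plus a column-wise
reduction over vertical offsets. This is bit-identical to a direct
footprint filter with neutral-element padding (out-of-frame pixels never
influence the result) and roughly two orders of magnitude faster at
radius 50.

**Auto-threshold** (method `"default"`). Per frame, on the 256-bin
histogram, the threshold is the *lowest* gray level t satisfying the
intermeans self-consistency condition

    t = round( (mean of pixels <= t) + (mean of pixels > t) ) / 2,

found by scanning upward from the darkest occupied bin (candidates are
clamped inside the occupied range so both classes stay populated; ties
round half up). Taking the lowest self-consistent point rather than
iterating from the overall mean matters in exactly the regime this tool
lives in: when spots cover a small fraction of the frame, the histogram is
dominated by the background mode and the mean-seeded iteration converges to
a spurious split *inside* that mode, flooding the mask; the bottom-up scan
instead lands between the small dark spot class and the background. With
`dark_background` off (default) spots are the dark class (mask = pixels
≤ t); with it on, the bright class. The mask is always True on spot pixels
regardless of polarity. A constant frame has no threshold: the result
carries an empty mask and a `degenerate` flag (this is how fully occluded
synthetic frames behave). Thresholding is strictly per frame — never pooled
across frames — so slow illumination drift cannot bleed between frames.

## Detection

Spots are detected per frame on the background-subtracted grayscale
(polarity-normalized so spots are bright), not on the binary mask — a blob
quality score is meaningless on binary input. The detector is a
single-scale Laplacian of Gaussian with σ = `blob_diameter` / (2√2), the
scale at which a disk of that diameter maximizes the (negated,
scale-normalized) response. Local maxima on the pixel grid with response
strictly above `quality_threshold` are kept after non-maximum suppression
at `min_separation` (default `blob_diameter`/2; the stronger peak wins,
ties break toward smaller (y, x)). Detections are integer-positioned and
ordered by (y, x); there is deliberately no sub-pixel refinement so runs
are exactly reproducible. Response is linear in image contrast, so
quality thresholds scale with footage contrast. Spots much larger than
`blob_diameter` (beyond roughly 1.5×) develop a ring of secondary maxima;
set the blob diameter near the largest expected spot size, or expect short
satellite tracks that carry no measurement weight.

Defaults follow the published protocol: blob diameter 10 px, quality
filter 0. The quality filter 0 is only sensible for clean footage — on
noisy video every positive noise ripple becomes a candidate. For the noisy
synthetic benchmark (noise σ = 10 gray levels, blur σ = 1 px) noise peaks
score below 5 while a real spot scores 30–70, so a quality threshold of 10
separates them with a wide margin; that value is used in the noisy
benchmark and is a reasonable starting point for footage of similar
contrast.

## Tracking

Frame-to-frame linking solves, for each consecutive frame pair, an exact
minimum-cost one-to-one assignment (Hungarian algorithm) with squared
Euclidean distance costs; pairs farther than `linking_max_distance`
(default 15 px, inclusive) are forbidden by a cost larger than any feasible
total, so the solver maximizes the number of links first and total cost
second. Unmatched detections start new segments. Gap closing runs the same
assignment between segment ends and later segment starts, allowed when the
frame difference is in [2, `max_frame_gap` + 1] (default gap 2 — at most
two consecutive missing frames) and the distance is within
`gap_closing_max_distance` (default 15 px, inclusive); merges chain
transitively and each bridged range is recorded as a `gap_span`. Track ids
are renumbered 1..N by (first frame, y, x of first detection), making ids
reproducible and independent of input order. No splitting or merging
events: tracks are simple chains.

## Measurement

For each track and each frame from its first to its last detection
(inclusive — frames inside gap spans use a linearly interpolated center), a
square search region of half-width round(radius) + `roi_offset` (default
20 px = twice the default blob diameter) is clamped to the frame and the
thresholded image inside it is analyzed: 8-connected components, area =
pixel count, perimeter = crack-boundary edge count (the number of pixel
edges separating foreground from background), circularity =
min(1, 4π·area/perimeter²), filtered by `min_area`/`max_area` and
`min_circularity`/`max_circularity` (permissive defaults). The measured
particle is the one containing the rounded track center, else the one with
the nearest centroid (ties prefer larger area). Color is the color frame's
pixel at the rounded center (a mean-over-particle mode exists behind
`color_mode="mean"` for noisy video). A particle whose bounding box touches
the search region is flagged `boundary_touch` — its area and color are
still recorded but the cell counts as unreliable and is excluded from
exports; a region with no acceptable particle yields `missing`.

**Circularity caveat.** The crack-boundary perimeter of any pixel set is at
least 2·(width + height) ≥ 4√area, so crack-based circularity never
exceeds π/4 ≈ 0.785 — the value attained by filled rectangles. A digital
disk has crack perimeter ≈ 8r and circularity → π²/16 ≈ 0.617 (0.565 at
r = 10): under this estimator *squares outrank circles*. The crack count
was chosen because it is exactly testable against an enumeration oracle;
the cost is that circularity here is not comparable to smoothed-perimeter
estimators (ImageJ's corner-corrected perimeter gives digital disks ≈ 0.9)
and the `min_circularity` filter must be set against this package's scale
(disk-like particles score ≈ 0.55–0.65, ragged noise blobs < 0.3). This is
a known, documented deviation; treat 0.785 as this estimator's "perfectly
compact" ceiling.

## Diagnostics and repair

`diagnose_tracks` counts cleanly measured frames per track and lists every
`missing`/`boundary_touch` cell. `update_roi` re-runs particle analysis for
one cell inside a caller-supplied region, upgrading it to `measured` only
if the selected particle keeps at least a one-pixel gap to the region
border on all sides (the border-contact rule is validated, never silently
fixed). `delete_track` removes a track and its rows without renumbering
the others. `auto_repair` is a batch convenience that retries each flagged
cell with a region enlarged by 25% per attempt (at most 3 attempts) — the
scriptable stand-in for stepping through frames by hand.

## Export

Two tables, rows = tracks and columns = frames labeled `Frame 1..N`
(1-based, matching spreadsheet convention; all internal indices are
0-based): surface area in px², and color as `"R,G,B"` text cells (or three
numeric columns per frame with `split_rgb`). Non-measured cells are empty,
never 0 — an empty cell means "not measured", and zero area would be a
measurement claim. Written as one xlsx workbook (sheets `Area`, `Color`)
or paired `_area.csv`/`_color.csv` files; measured values round-trip
exactly. The overlay render draws each measured particle's 1-px contour in
magenta with a `track_id: area` label, and the search-region rectangle in a
distinct color for cells without a particle; pixels outside drawn
annotations are untouched.

Video I/O reads numbered PNG/TIFF frame directories and uncompressed
24-bit RGB AVI files through a small built-in RIFF codec (compressed or
audio-bearing AVIs are rejected with instructions to re-export
uncompressed); round-trips are bit-exact. Frame rate is carried as
metadata only — every series in this package is per frame, not per second.

## Synthetic scenes and what they do (not) show

The generator renders dark hard-edged disks (pixel included iff
(px−x)² + (py−y)² ≤ r² at pixel centers) on a light background, with
per-spot radius dynamics (constant, logistic expand/retract, pulse),
optional jitter or drift motion, Gaussian blur, additive Gaussian noise,
and scripted occlusions (frames where a spot simply is not drawn). Hard
disks make the true area an exact integer (`truth_area` shares the same
inclusion rule), so measurement can be tested for *equality*, not just
closeness. Default scene: 20 spots of radius 5 px, 50 frames, 128×128,
pairwise center separation ≥ 2·r_max + 4 px, noiseless — deliberately
small so the full benchmark suite runs in seconds on one CPU, while still
exercising every pipeline stage. Identical seed and parameters give
bit-identical video and truth.

What passing on these scenes does **not** show: robustness to the textures
of real skin footage — uneven illumination, out-of-focus spots,
anti-aliased edges, overlapping chromatophore layers (a larger expanded
organ can fully hide a smaller one below it — a 2-D method cannot see
through it), camera shake, or compression artifacts. The synthetic
occlusion model (spot absent for whole frames) is a stand-in for those
transient losses, chosen because it has exact ground truth.

## Numerical and degenerate-input choices

- Distance caps are inclusive (≤); a restart at exactly 15.0 px merges.
- Histogram mean ties in the threshold round half up.
- Assignment, suppression and ordering ties all break deterministically
  toward smaller (y, x); no stage uses unseeded randomness.
- A constant frame yields an empty mask plus a degenerate flag, not an
  arbitrary threshold.
- `radius 0` disables background subtraction; a radius exceeding the frame
  warns but proceeds.
- Circularity is clamped at 1.0 (unreachable under the crack estimator,
  kept for interface stability if another estimator is added).
- Pipeline problem sizes in the test-suite benchmarks (128×128, 50 frames,
  ≤ 20 spots) are the package's chosen benchmark conditions; all scale
  linearly in pixels × frames.
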