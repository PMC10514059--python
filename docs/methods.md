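# Methods

This note records the models, conventions and numerical choices behind
`cellmodes`, in the order data flows through the package.

## Coordinate and unit conventions

Masks are binary images with `x` = column, `y` = row, origin at the
center of the top-left pixel; frames are 0-based. Lengths are in µm
(scaled by the pixel size, default 0.65 µm/px), times in seconds
(frame interval Δt, default 90 s), speeds in µm/min, angles in degrees.
Angles are counterclockwise-positive *in (x, y) coordinates*; because
image y points down, a positive turn appears clockwise on screen. The
convention matters because signed turning-angle medians are reported.

## Morphometrics

* **Centroid** — unweighted mean of foreground pixel centers.
* **Area** — foreground pixel count × pixel_size².
* **Perimeter** — length of the marching-squares iso-contour at level
  0.5 after a 5-point circular moving-average smoothing of the polyline.
  Raw marching-squares polylines overestimate smooth perimeters by ~5 %
  (stair-stepping); the smoothed estimator is within 0.3 % on a disc of
  radius 50 px and within ~2 % on rectangles. The estimator name is
  recorded in the feature-table metadata. Absolute perimeter-derived
  quantities (P/A) depend on the estimator; published values from other
  estimators can only be compared rank-wise.
* **Moment-equivalent ellipse** — from the second central moments of the
  pixel set with the per-pixel 1/12 variance term (pixels as unit
  squares, not points); semi-axes a = 2√λ₁, b = 2√λ₂. Degenerate
  (collinear) pixel sets are floored at a half-pixel minor axis.
* **Elongation** — ε = 1 − b/a. The source formula is sometimes printed
  as 1 − a/b with a the major axis, which is negative for every
  non-circular shape and contradicts the stated anchor cases (0 for a
  circle, → 1 for a needle); 1 − b/a satisfies both anchors and is used
  throughout.
* Masks with several connected components keep the largest (satellite
  pixels are tracking artifacts) with a warning.

## Kinematics

vₙ = ‖rₙ₊₁ − rₙ‖ / (Δt/60), undefined at the last frame. θₙ is the
signed angle from (rₙ − rₙ₋₁) to (rₙ₊₁ − rₙ) via atan2(cross, dot),
wrapped to (−180°, 180°]; frames flanked by a zero-length displacement
get NaN rather than 0, which would spuriously sharpen the dispersion
statistics. Centroids are used unsmoothed.

## Behavioral classification

The three behaviors are defined by *dynamics*, judged over a window of
the two previous and two following frames (truncated at track ends but
never below three frames):

* **D** net displacement ÷ path length of the measured centroid over the
  window (directional vs non-directional displacement);
* **X** expansion anisotropy: the circular resultant length of the
  directions (from the cell centroid) of pixels newly occupied between
  consecutive masks, pooled over all newly occupied pixels of the
  window's steps (uni- vs multidirectional border extension);
* **S** mean Jaccard (intersection-over-union) overlap of consecutive
  aligned masks (stable vs unstable shape);
* **A** mean area (spread vs poorly spread); **PA** mean P/A is carried
  along for reporting.

Three implementation details make X usable on pixelated masks:

1. **Alignment.** Masks are aligned at sub-pixel precision by the
   measured centroid displacement, then refined by a ±3-px integer
   search maximizing overlap. The refinement is essential, not
   cosmetic: one-sided border growth drags the centroid toward the new
   material, so exact centroid alignment manufactures a
   counter-directional "rear crescent" of apparently new pixels whose
   vector sum cancels most of the genuine signal — capping the
   resultant near 0.15 even for perfectly unidirectional extension.
   Overlap-refined alignment anchors the comparison on the unchanged
   cell body instead. Ties in the search prefer the smallest shift, and
   the crop box is padded beyond the search radius so shifting cannot
   shrink the union.
2. **Flicker guard.** Rasterized (and segmented) outlines flicker by
   ±1 px along the entire contour between frames; those pixels would
   read as isotropic expansion of ~100–300 px per step and drown the
   signal. Newly occupied pixels must therefore clear a 1-px dilation
   of the previous mask.
3. **Extension floor.** If fewer than 24 new pixels survive in the whole
   window there is no appreciable extension, and X is defined as 0
   (a handful of noise pixels is not evidence of unidirectionality).

The decision ladder (amoeboid instability checked first, because
directed motion with an unstable shape would otherwise partially satisfy
the mesenchymal clause):

1. AMO if S < s_lo and D ≥ d_hi
2. MES if D ≥ d_hi and X ≥ x_hi and S ≥ s_hi and A ≥ a_spread
3. POL if D < d_hi and X < x_hi and S ≥ s_hi
4. UND otherwise, or when features are undefined.

Raw labels are smoothed by a width-3 categorical median filter, then
runs shorter than `debounce_min_run` are absorbed into the nearest
*identified* flanking state (UND marks ignorance, not a behavior, so a
brief identified run flanked by UND is not erased into UND).

Defaults are d_hi = 0.5, x_hi = 0.5, s_hi = 0.6, s_lo = 0.35,
a_spread = 300 µm², debounce_min_run = 2 — generic, deliberately not
tuned to any particular imaging setup. For quantitative work
`calibrate_thresholds` grid-searches the cutoffs against ground-truth
labels (maximizing frame-wise balanced accuracy, deterministic given the
grid, which contains the defaults); the benchmark routines calibrate on
pure-state synthetic movies so every class contributes equally, and use
a debounce floor of 5 frames ≈ the classification window span (7.5 min
at 90 s — shorter label runs cannot be distinguished from window
mixing). When counting transitions on *classified* sequences,
unidentified gaps up to debounce + window span − 1 = 8 frames bridge a
visit, because a true switch necessarily produces a few ambiguous
windows; for ground-truth-style sequences the default bridge stays at
2 frames.

Inclusion criteria: frames with cell–cell contact, or division in the
same or a neighboring frame, are excluded; non-individual cells are
dropped entirely; a missing annotation table means all frames are valid
(warned once).

## Population statistics

Per-state durations are frame counts × Δt summed across visits (1-h
histogram bins with a closed top bin at the movie length). Occurrence
shares divide per-state frame counts by all frames, with √count error
bars. Occupancy time series are per-frame shares across cells (they sum
to 1 and are therefore compositional: their Pearson correlations carry a
`dependent_series` flag and should be read as descriptive). Quartiles
use linear interpolation (recorded in metadata); IQR = Q3 − Q1 by
construction. Mann–Whitney comparisons are two-sided, exact for untied
samples up to n = 20 per group and tie-corrected asymptotic otherwise,
starred at 0.05/0.01/0.001. No multiple-testing correction is applied.

## The synthetic generator

The generator emulates the study conditions: 4-h movies at 90-s
intervals (161 frames), 50 cells per condition, 0.65 µm/px, two presets
("glass-like" and "PA-like", the latter emulating a 40 kPa
polyacrylamide substrate).

**States** follow a per-frame Markov chain. Off-diagonal rates are set
by detailed balance so the stationary distributions match the published
occupancies (glass ≈ 58/33/9 % MES/POL/AMO; PA ≈ 26/48/26 %), the
dominant transition is MES↔POL on glass and POL↔AMO on PA, expected
transitions per cell are ≈ 1.4–1.6, and direct MES↔AMO switches occur in
≈ 3 % of cells per movie.

**Motion** is a persistent random walk: per-frame speed log-normal
around the state median (medians and log-spreads from the published
per-state quartiles), heading incremented by a wrapped-normal angle
(spread = published IQR/1.349; mean = the published, slightly negative,
median turning angle — exposed as a free drift parameter, with no
mechanistic claim). Trajectories are reflected at a canvas margin, with
a log warning.

**Centroid scatter.** The measured centroid of a protrusive cell
fluctuates around its motion track. Each state has a shape-driven
centroid scatter (largest, 0.42 µm/axis, for the polygonal state whose
"motion" is mostly border dynamics); the intrinsic walk speed is reduced
so that the *measured* per-frame displacement median — Rice-distributed
given the scatter — stays on the configured value. This is what makes
polygonal centroid motion read as non-directional on 5-frame windows
while keeping its measured speed median on target. The polygonal
per-frame speed log-spread is set to 0.50, below the published pooled
value, because the scatter contributes the remainder of the measured
spread and a heavier intrinsic tail produces single-jump-dominated
windows that read as directional.

**Shapes** are star-convex radial profiles: a base ellipse times
(1 + low-order Fourier boundary noise) times (1 + protrusion bumps):

* MES — a leading fan of 3 bumps within ±25° of the (slowly tracking,
  EMA 0.02/frame) body orientation, whose amplitude ramps up over ~5
  frames and collapses (protrusion–attachment cycles); the ramp's
  stationary phase law is kept near-uniform so mid-ramp calibration is
  unbiased.
* POL — 2–5 lobes at fixed, near-symmetric directions (antipodal for
  the bigonal case) breathing slowly *in phase*: the border advances in
  several directions at once, a fraction of a pixel per frame.
* AMO — 3–7 bleb-like bumps, boundary modes, apparent axis and
  elongation all re-sampled with probability 0.92 per frame.

A per-visit affine correction (full covariance whitening in the body
frame, calibrated once against a mid-cycle nominal pattern) puts the
moment ellipse on the per-cell target elongation and area without
cancelling the per-frame protrusion dynamics the classifier reads; the
amoeboid state, whose pattern is transient anyway, is whitened every
frame. Downstream per-state medians of speed, area and elongation land
within ±10 % of the configured targets (verified at 30 cells × 55
frames per state; cell-to-cell parameter scatter dominates the median's
sampling error, so cells matter more than frames).

**What the generator does not emulate:** real brightfield appearance and
segmentation error beyond boundary flicker; cell–cell interactions
(contact/division flags are injected as annotations only, without
morphological rendering); absolute perimeter richness of real outlines
(P/A levels are rank-faithful, not absolute); within-state behavioral
substructure (e.g. the diversity of mesenchymal cells); any mechanistic
cause of the negative turning-angle medians. Passing recovery tests on
this generator therefore demonstrates that the pipeline recovers *the
encoded contrasts* — not that the thresholds transfer unchanged to any
particular microscope; recalibration on annotated data is the intended
route there.

## Benchmarks

The recovery benchmark (50 cells × 161 frames, glass-like) calibrates
thresholds on a held-out pure-state set (5 cells × 70 frames per state,
seed offset +101), classifies every movie, and scores (i) frame-wise
balanced accuracy excluding frames within two frames of a true switch
(the window necessarily mixes states there) and (ii) the fraction of
cells whose recovered transition count is within ±1 of truth. Typical
values across seeds: 0.88–0.92 and 0.88–0.92. The empirical transition
matrix of a 3×10⁴-step chain recovers T to max-abs error < 0.01.

## Known limitations

* The decision ladder is an AND-conjunction of noisy features; per-frame
  recall near behavioral switches is structurally limited, which is why
  transition-adjacent frames are excluded from the frame-wise score and
  why track-level debouncing is integral, not cosmetic.
* D on a 5-frame window has high variance; mesenchymal and polygonal
  directionality distributions overlap for any threshold, and the X and
  S features carry much of the separation.
* Occupancy correlations are compositional by construction; their
  p-values are reported but flagged.
* The elongation of extremely spiky shapes is a moment-ellipse summary;
  two visually different outlines can share ε.
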