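# Methods

This note documents the models, algorithms, parameter defaults and
numerical choices behind `platescreen`, and what the synthetic-data
tests do and do not demonstrate about real plate photographs.

## Imaging model (synthetic_plate)

The generator emulates transilluminated white-box photography of an
arrayed plate: a bright agar rectangle (default intensity 150/255) on a
darker surround (40), with colonies brighter still (peak 230). The
scene is modulated multiplicatively by a planar illumination gradient
(default amplitude ±12% corner-to-corner) plus one Gaussian blob
(amplitude 10%, σ = 120 px) standing in for the camera's reflection in
the diffusor box; additive Gaussian pixel noise (σ = 2 intensity units)
and 8-bit quantization complete the image. The plate may be rotated by
a small angle (positive = counterclockwise in x-right/y-down image
coordinates) and each colony center carries Gaussian pin jitter
(σ = 0.3 px).

**Colony profile.** A colony of radius R is a flat-top disk: full
contrast out to 0.75 R, then a cosine shoulder that reaches the agar
level exactly at R. A faint 2-unit pedestal covers the whole disk
interior — a thin translucent rim — so the above-agar footprint of a
noise-free render is exactly the pixel disk of radius R. Without the
pedestal, 8-bit rounding absorbs the shoulder tail into the agar level
and the rendered footprint undershoots πR² by ~2.5%, which would make
"area = pixels above background" systematically biased at the source.
Overlapping colonies compose by maximum, producing the saddle-shaped
intensity profile between merged neighbors that the bounding step
detects. True area is recorded as πR²; per-colony rendered counts
deviate from it by lattice quantization (±2% at R = 8), which is why
truth-consistency checks are aggregate, not per-pixel.

**Growth.** Mean radius follows a saturating curve
r(t) = r₀·√(1 + (F−1)·g(t)) with g(t) = (1−e^(−t/τ))/(1−e^(−T/τ)), so
median colony *area* grows exactly F-fold between pinning and the final
time T = 48 h. The per-density defaults (`STANDARD_CURVES`) encode the
study conditions the package targets: the 6144 format reaches ~7-fold
area growth by its 12-h analysis point with overgrowth just beginning
(mean diameter ≈ 0.91 of the 14-px spacing); the 1536 format is
analyzed at 48 h with ~8-fold growth and no overgrowth; the
hyper-density 24,576 format begins merging within 3–6 h and is analyzed
at 3 h. Per-colony size scatter is lognormal with cv = 5% (drawn once
per plate, reused across time points of a timecourse, so fold-growth
round-trips exactly); strain fitness effects multiply area; up-scaled
plates multiply each interleaved source subgrid (position (r,c) →
source 2·(r mod 2)+(c mod 2)) by its batch factor.

**Scale.** The default 6144-format render uses 14 px center-to-center
(≈1.9 Mpx canvas): large enough for sub-pixel position tests, small
enough that the full suite runs in minutes. The pixel pitch is a free
parameter; the acceptance script renders at 42 px spacing (≈14 Mpx),
the resolution class of the SLR photographs the scene emulates, where
crop quantization is negligible for angle recovery.

**Not emulated:** agar texture, colony morphology (color, fluffiness,
lobed edges), off-nominal artifacts (smears, cross-contamination,
condensation), lens distortion, JPEG blocking (a JPEG-quality knob
exists but tests use lossless PNG). Passing tests demonstrate
correctness of the geometry, thresholding and statistics under a
faithful but idealized optical model — not robustness to every failure
mode of real photographs.

## Cropping (image_ingest)

Candidate thresholds are midpoints between adjacent prominent modes of
the smoothed intensity histogram (9-bin triangular kernel, modes below
1% of the tallest peak ignored), tried darkest-first; a threshold is
accepted when its largest 8-connected bright component covers ≥ 50% of
the frame — that component is the plate and its tight bounding box is
the crop, which is what makes the corner-touching contract hold for
rotated plates. If modes exist but no threshold isolates a plate-sized
region, the frame is already plate-tight and is returned unchanged
(identity crop), making cropping idempotent. A near-constant image
raises a crop error. Known limitation: re-cropping an *already cropped*
heavily overgrown plate can shave the margins, because its merged
colony grid is itself a plate-sized bright component.

## Grid alignment (grid_align)

The closed form θ = atan((r·Y − X)/(r·X − Y)) was re-derived from the
crop decomposition X = W·cos θ + H·sin θ, Y = W·sin θ + H·cos θ with
W = r·H; it is exact (validated to 1e−6 degrees against the forward
trigonometry). The tight crop of a rotated rectangle is identical for
±θ, so the closed form recovers |θ|; the sign is resolved by scoring
both candidate grids against the image foreground (total excess
intensity in 3×3 windows at predicted positions) and keeping the
better. Grid corners are placed assuming the margin between the
outermost colonies and the plate edge is 3.5 spacings (configurable;
the generator uses the same default, and corner errors up to half a
spacing are absorbed by the iterative fit).

The iterative fit alternates (a) predicting all positions from the
affine model, (b) assigning each foreground pixel (above a plate-level
cutoff at median + 0.4·(p99.8 − median)) to its nearest grid position
under the inverse affine map and snapping positions whose cell captures
≥ 1% foreground to the intensity-weighted centroid — a unique
tie-break on plateaus — and (c) refitting the affine model by least
squares; it stops when the mean position change drops below 0.1 px
(cap: 10 iterations; typically 2–3). Positions without signal stay at
the affine prediction, so empty positions are never snapped to noise.

## Colony quantification (colony_quant)

Background: per-position window of side 2 spacings; unit-bin histogram
smoothed with a 5-bin triangular kernel (a flat boxcar would turn a
single-valued background into a plateau with no unique mode); the
lowest local maximum above a small floor is the background mode,
refined by parabolic interpolation; σ comes from the second moment of
the left half-peak only, since the right half is contaminated by colony
and shoulder pixels. The threshold is μ + k·σ with k = 4 — the
one-sided normal tail at 4σ is ~3×10⁻⁵, i.e. well under one false
pixel per window — and μ + 1 intensity unit when σ = 0 (the original
toolkit's exact offset rule is unpublished; k·σ is this package's
documented choice, validated by synthetic recovery).

Bounding: for each neighbor direction, the median intensity profile
over a 5-px band between the two centers is scanned for a minimum
strictly between the two intensity peaks; it counts as a saddle only if
it dips below both peaks (otherwise a colony's own shoulder would pose
as a second peak), ties resolve toward the midpoint, and positions
without a saddle or without a neighbor colony default to the
half-spacing midpoint. Grid-border positions use the half-spacing
extent outward and are flagged `edge`. Area is the integer count of
in-box pixels above threshold (no sub-pixel refinement); `empty` flags
areas < 5 px, `overgrown` flags foreground touching ≥ 3 box edges.

A reference global-threshold measurer (single Otsu cutoff, half-spacing
boxes) is kept for comparison; on gradient + reflection scenes its
truth correlation falls visibly below the dynamic method at both the
low-contrast start (0 h) and overgrown end (48 h) of a timecourse —
the motivating property of per-colony thresholds.

## Normalization

Stages are enforced in order raw → plate_normalized →
spatially_corrected (→ source_corrected), recorded in a provenance
list. Medians serve as every center statistic (robust to genuine
mutant effects); the plate statistic excludes the outermost ring, which
grows systematically differently. The spatial surface is a 9×9
grid-position moving median (common practice for arrayed-screen spatial
effects), NaN-aware, truncated at borders, with a plate-median fallback
for all-missing neighborhoods; division by the surface removes smooth
nutrient/illumination trends while a 9×9 median passes isolated mutant
effects through (a fitness-0.5 colony among wild types retains its
value within 10%). Re-applying the correction changes values by < 1%
on average; individual border positions can move a few percent because
truncated windows hold as few as 25 samples. Missing values propagate;
no stage imputes. Source correction deinterleaves the four source
subgrids, runs plate + spatial normalization on each as an independent
lower-density plate, and re-interleaves; it requires an up-scaled
format (≥ 4×1536).

## Screen statistics (fitness_stats)

Fitness = mean of a strain's pooled replicate corrected sizes divided
by the control pool's median; p-values come from Welch's two-sample
t-test against the control pool — chosen over pooled-variance t because
the control sample is typically far larger than n per strain. The
minimal detectable difference uses the standard equal-variance,
equal-n two-sample form MDD = t(1−α/2, 2n−2)·σ·√(2/n) (the concept's
defining formula is not published; this is the conventional choice).
Resolvable fraction counts raw p < α by default — no multiple-testing
correction, matching common screen reporting — with Benjamini–Hochberg
(via `scipy.stats.false_discovery_control`) behind a flag. Dynamic
range is the 2.5–97.5 percentile spread of strain fitness. The cost
model charges each plate 2 units plus 1 unit per pad pinning (one pad
for dedicated-density pads, four for 4-to-1 up-scaling); pads are
consumables, reuse is not modeled.

## Problem sizes used in validation

The test suite renders full 6144 plates (~1.9 Mpx) for the grid,
thresholding and end-to-end checks, one 24,576 plate for hyper-density
alignment, and uses truth-only (unrendered) tables for the statistical
calibrations: a 1000-strain × 6-replicate null screen for type-I
calibration, and a 6-plate 6144 screen (1152 strains in quadruplicate,
10% carrying fitness 0.8) for end-to-end recovery — the replicate
structure of a real ultra-high-density screen, where each strain is
pinned in quadruplicate from its 1536-format source. These sizes were
chosen so the full suite completes in a few minutes on one CPU while
every check still runs at the density it is about.

## Known limitations

- The optical model is idealized (see above); algorithm robustness to
  real-world artifacts beyond gradients/reflection/noise is untested.
- Rotation handling targets |θ| ≤ ~2°; the closed form degrades as
  θ → 45° and sign resolution needs visible colonies.
- Area is pixel-integer; at hyper-density (colony radii ~2.5 px)
  lattice quantization dominates size noise, mirroring the pixelation
  noise real hyper-density images suffer.
- Cross-plate batch correction and replicate merging beyond pooling,
  epistasis scoring, and time-series growth modeling beyond fold-change
  are out of scope.
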