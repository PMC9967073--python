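# Methods

This note records the models behind `lfm3d`, the parameter choices that
matter, what the synthetic captures do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Light-field model and conventions

A focused-MLA capture is treated as an ideal 4D light field
L(s, t, u, v): the lens index (u, v) is the spatial sample and the pixel
inside a lens (s, t) the angular sample, so an orthographic view has one
pixel per lens (a 76×76-lens capture yields 76×76-px views). All indices
are 0-based, (row, col)-ordered, origin top-left. The central view index
is (⌊Ns/2⌋, ⌊Nt/2⌋); for even angular counts this picks the upper-left of
the central 2×2 — an arbitrary but fixed convention. Rasters that do not
tile exactly (e.g. a 4000 px sensor over 76 lenses) are center-cropped,
never resampled: interpolating angular data would blur parallax.

## Refocusing

The refocus parameter α labels virtual image planes; the native
(MLA-conjugate) plane is α = 1. Refocusing shears the light field by
β(α) view-pixels per angular index and averages the views. Two shear
conventions are supported; the default is `linear` (β = α − 1), under
which the in-focus α is an affine function of object-space displacement
whenever disparity is linear in depth — the property the distance
calibration relies on. The plenoptic `reciprocal` convention
(β = 1 − 1/α) is available. α labels are kept positive; grid values whose
linear-convention label would be ≤ 0 are dropped.

Two routes compute the same integral:

- **shift-and-sum** (spatial): each view is resampled with a B-spline
  interpolant and averaged; samples that fall outside a view are excluded
  and the per-pixel mean renormalized over the remaining views, avoiding
  darkened borders that would bias the focus measure. The default
  interpolation is cubic (order 3). Bilinear (order 1) is available but
  its resampling error (~10⁻³ on band-limited content) is two orders
  larger than cubic's and would dominate any cross-route comparison.
- **Fourier slice** (frequency): the 2D spectrum of the refocused image
  is the slice of the 4D light-field spectrum along the sheared
  trajectory. The slice is evaluated exactly — per-view 2D FFTs combined
  with the analytic phase ramps — rather than interpolated from a gridded
  4D FFT, so the route introduces no slicing error of its own. Views are
  zero-padded by the maximal shift to suppress periodic wrap-around
  (`pad=0` treats them as periodic).

On periodic band-limited fields (spectrum support |k| ≤ 2 on 16-px
views) the routes agree to ≲ 5·10⁻⁵ RMS, limited by the cubic spline;
they serve as mutual oracles in the tests. On non-periodic data the
comparison is interior-only, since the exclusion-renormalized and
zero-padded boundary treatments legitimately differ.

Default α grid: 64 planes uniform in β, with β_max set so the largest
view shift is a quarter of the view width; both are configurable, and the
simulator fixtures use `fixture_alpha_grid`, which covers the phantom's
disparity range with a 0.5-view-pixel margin.

## Depth estimation

**Focus measure.** Per plane, the squared response of the 3×3
five-point Laplacian summed over a window (default 9×9, reflect-padded).
The window trades localization against noise; 9×9 suits the strong noise
and low resolution of LFM views.

**Initial depth.** Per-pixel argmax over α; ties break toward the
smallest α (the first index), a documented determinism choice.

**Reliability filter.** A pixel is kept iff (a) its peak focus value is
at least `tau` (default 1.0) times the global median peak, and (b) its
peak-to-mean ratio along the α axis is at least `prominence_ratio`
(default 1.5). Criterion (a) removes texture-poor pixels whose maxima are
noise; (b) removes pixels whose focus profile is flat (e.g. a surface
with no parallax contrast, for which every refocus plane looks alike).
Kept pixels receive a common precision λ = 10³; with matting affinities
of order 1 this makes observations essentially hard constraints while
keeping the system well-conditioned. All three are config keys.

**Matting Laplacian.** The closed-form-matting affinity of the central
view: for each full 3×3 window with color mean μ and covariance Σ,
pixel pairs accumulate (1 + (Iᵢ−μ)ᵀ(Σ + ε/9·I₃)⁻¹(Iⱼ−μ))/9, and
L = diag(W·1) − W. Defaults: window radius 1, ε = 10⁻⁵ on [0, 1]
intensities — the standard setting. Building L as diag(row sums) − W
makes the zero-row-sum property exact by construction; symmetry is
enforced exactly by averaging W with its transpose (pure floating-point
commutativity, no value change).

**MAP solve.** (L + Λ)d = Λd̃ via a sparse direct factorization below
10⁴ unknowns and Jacobi-preconditioned conjugate gradients (rtol 10⁻⁹,
direct fallback) above; the relative residual is verified against 10⁻⁸
either way. One caveat worth recording: L is *not* an M-matrix (window
affinities can be negative), so the solution does not obey a discrete
maximum principle — on adversarial random guide images the dense map can
overshoot the observed range by O(0.1·range). On natural guide images the
overshoot is tiny; `estimate_depth` clips the result to the α-grid span.

Depth is estimated at view resolution (one value per lens); upsampling to
the 2D-image resolution happens at model-building time. Depth values are
carried as real-valued α throughout and only quantized on export.

## Distance calibration and measurement

The α→mm map is fitted by ordinary least squares, slope and intercept
(`scipy.stats.linregress`); a slope-only mode exists for strict
single-coefficient replication, but a pure scale cannot absorb the
arbitrary origin of the α axis, so the affine fit is the default. ROI
representatives are 80 % trimmed means (trim fraction configurable) —
robust to the salt outliers that focus failures produce. ROI rectangles
are 0-based half-open. Measurement reports the ROI mean height above a
stated baseline and the per-pixel mean absolute error against the
reference height.

Discrete entropy quantizes an image into `levels` bins over its own
min–max range (depth maps are not natively 8-bit; an absolute-range mode
exists for byte images) and returns −Σ p log₂ p in bits: 0 for constant
images, log₂(levels) at most.

## Reconstruction and display rendering

Bicubic depth upsampling clips its output to the input range (cubic
overshoot would invent depths no pixel has). Holes are filled by Coons
patches: each connected hole's bounding-box frame supplies four boundary
curves, and the Coons surface through them replaces the hole —
affine/bilinear surfaces are reproduced exactly. Border-touching holes
have no complete frame and fall back to nearest-valid extension with a
warning.

The point cloud places one point per retained pixel at
(col·scale, row·scale, depth). Layering bins z uniformly into n layers
(each point in exactly one bin; within a lateral cell the nearest point
wins, far-to-near stable write order for determinism). The default layer
count makes each slab one α-grid step of metric depth, capped at 128.

The display is a pinhole-lens model: lens sheet at z = 0, panel at
z = −gap, rays through lens centers, no diffraction or aberrations.
`place_scene` maps a specimen cloud into display space by a uniform
similarity: footprint scaled to 90 % of the lens-array aperture, depth
extent centered on the panel's thin-lens conjugate plane. DRC casts
exactly one ray per EIA pixel (instrumented with a counter), visits
layers nearest-first, takes the first occupied nearest-neighbor cell, and
stops — occlusion by construction. Elemental images are independent; the
implementation renders them serially, and tests pin the output to a
plain-loop z-buffer oracle with the same sampling rules. EIA pixels per
lens default to ⌊lens pitch / pixel pitch⌋ (1 mm / 0.089 mm → 11).
Preview views use the reverse pinhole mapping — one pixel per lens per
viewing angle — as a software stand-in for the physical display.

## The capture simulator

The simulator emulates a Lambertian, occlusion-free textured height
field h(x) imaged by a pinhole lens array: view (s, t) samples the
texture at x − γ·(h(x) − z₀)·((s, t) − center), bilinear, with i.i.d.
additive Gaussian noise clipped to [0, 1] as an option. γ (view-pixels of
disparity per angular index per mm) is a free parameter: a real
instrument ties it to the objective NA and MLA pitch, but no optical
transfer model is part of the package. Depth→disparity is exactly linear
by construction, so the true calibration line is mm = α/γ + (z₀ − 1/γ)
under the linear shear convention.

Default conditions: 76×76 lenses (hence 76×76-px views, matching the
instrument's active area), 7×7 intra-lens pixels, γ = 1, z₀ = 0,
noiseless. The angular resolution is reduced from the instrument's 52×52
to keep the full chain at desk scale; parallax information, not angular
sample count, is what the pipeline consumes. Fixtures: a 4-floor, 1 mm
staircase for calibration; 1 mm triangular, 2 mm cylindrical and 3 mm
square columns for measurement; a flat plane. Phantoms carry a 12-px
margin beyond the active field so off-plane parallax can sample real
texture instead of clamped edges (the physical analogue: the specimen
extends beyond the 76×76 active window of the 100×100 MLA).

Two deliberate departures from a "single continuous texture" phantom:
the staircase floors share one texture (color edges are not needed for
calibration ROIs), but the measurement columns are recolored on their
footprint (channel rotation plus a small cast, preserving texture
amplitude). The matting-based densification propagates depth along color
structure; a scene whose depth edges have no color counterpart violates
the method's stated operating assumption, which real printed boards (a
different material from the ground) do not. Measurement ROIs are the
footprint core, eroded by the parallax extent plus the focus half-window:
near the rim, views mix foreground and background texture and
shape-from-focus is unreliable — the same reason physical measurement
ROIs sit mid-board.

What the simulator does **not** emulate: self-occlusion at step edges,
vignetting and illumination falloff (available as an option, off by
default), wave-optics PSF, chromatic effects, demosaicing, MLA
misalignment. Passing tests therefore demonstrate the correctness and
internal consistency of the processing chain under its stated
assumptions, not robustness to every artifact of a physical capture.

## Problem sizes and determinism

The test suite and the acceptance script run the full chain at 76×76
lenses with 7×7 views and 64 refocus planes (seconds per pipeline run),
cross-checks on ≤ 16×16-lens fields, matting/solver oracles on ≤ 12×12
images, and rendering oracles on ≤ 8×8-lens displays with ≤ 3 layers —
sizes chosen so every oracle (dense eigensolvers, dense direct solves,
plain-loop renderers) is exact and fast. Every stochastic component draws
from an explicit `numpy` Generator seed; the whole chain is
bit-reproducible given seed and config.
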