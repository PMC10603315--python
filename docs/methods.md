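# Methods

This note documents the estimators, models and numerical choices behind
`chemoguide`, and what the synthetic-data validation does and does not
demonstrate about real microscopy data.

## Coordinate and angle conventions

Pixel (0, 0) is the top-left corner; x increases along columns and y
increases *downward* along rows (raster order). All trigonometry is done
in a y-up mathematical frame obtained by negating y, so angles are
measured counter-clockwise from +x. Fiber orientations are axial
(nematic: a fiber has no head), defined modulo 180° and reported in
(−90°, 90°]. All lengths are micrometers and times hours past the I/O
boundary; the default pixel size, 1.074 µm/px, corresponds to a
1.1 × 1.1 mm field imaged at 1024 × 1024 px and is applied with a logged
warning when no calibration is given. The inward radial unit vector −r̂
from the device geometry defines the chemotactic gradient direction
everywhere.

## Structure-tensor orientation and coherence

The local texture tensor is J = W ∗ [IxIx, IxIy; IxIy, IyIy], with
gradients computed as Gaussian derivatives at `gradient_sigma_px`
(default 1 px — small enough to resolve individual fibers) and the
window W a Gaussian at `window_sigma_px` (default 8 px, roughly one
fiber spacing at 10× magnification). Both are configuration-exposed and
recorded in run manifests, because absolute coherence values depend on
the window scale: comparisons of coherence magnitudes across studies
must sweep the window. Boundaries use reflective extension, and a margin
of one window sigma is excluded from radial profiles as
boundary-contaminated.

The fiber direction θ_p is the eigenvector direction of the *smaller*
eigenvalue (minimal intensity variation is along a fiber), and coherence
is the normalized eigenvalue contrast, with the 0/0 case (zero tensor
energy) defined as 0. Pixels below a tensor-energy quantile (default:
the lowest 50%) are excluded from profiles — coherence is meaningless
where there is no fiber signal; how background was handled is otherwise
an open choice and this one is explicit and logged.

Δθ, the angle between θ_p and the radial direction, is the axial
difference min(|δ|, 180° − |δ|) folded to [0°, 90°]. Profiles report
both the mean angle in degrees and the mean cosine, for comparability
with cosine-based summaries.

The implementation is verified against an independent brute-force oracle
(analytic Gaussian-derivative kernels, explicit nested-loop correlation,
edge-duplicating reflective padding) to 1e-8 on small images, and
against analytic identities: parallel stripes give c = 1 to 1e-6, white
noise stays below the c = 0.2 alignment threshold and decreases with
window size, 90° rotation is equivariant and affine intensity changes
are invariant.

## Cell morphology

Segmentation: Otsu (or fixed) threshold, hole filling, 8-connected
labeling, then automated filters — border-touching components dropped,
area within [100, 10000] µm², solidity ≥ 0.3 — each decision logged per
object. These filters replace manual screening of connected components,
which is not reproducible; the defaults keep single MDA-MB-231-scale
cells and reject debris and clumps.

Perimeter: length of the marching-squares sub-pixel contour (0.5 level)
smoothed by a periodic Gaussian (σ = 2 px along the contour). Raw
pixel-edge counting overestimates smooth perimeters by ~7%
(staircase effect), which would bias circularity low by up to ~14%; the
smoothed contour is within ~1% on discs and 4:1 ellipses (calibrated by
the disc/square/ellipse oracle tests). The duplicated closing vertex of
the traced contour is dropped before smoothing so the filter is exactly
cyclic, making the estimate invariant under 90° rotations.

Aspect ratio: major/minor axis ratio of the moment-equivalent ellipse
(from second central moments), chosen over bounding-box or Feret ratios
because the protrusive classification compares against the ideal-ellipse
reference curve at the same aspect ratio. Exactly isotropic moment
tensors return exactly 1; line-like degenerate masks return a large
finite capped value with a warning. The ellipse reference circularity
uses the complete elliptic integral of the second kind (machine
precision), verified against independent quadrature.

A cell is *strongly protrusive* iff its circularity is strictly less
than 0.8 × the same-aspect-ratio ellipse circularity. Population
fractions (aspect ratio > 3, > 6, protrusive) are computed per
cell-frame observation — each time a cell is sampled counts once.

## Trajectories and chemotaxis index

Linking is greedy mutual-nearest-neighbor between consecutive frames,
with links longer than `max_step_um` (default 30 µm ≈ 3× the mean
hourly step) rejected and ties broken deterministically by lowest index.
A missed frame terminates a track: trajectories are contiguous with
constant spacing and no interpolated positions (interpolation would
fabricate displacement). On simulated cohorts with realistic spacing the
linker recovers ≥ 95% of ground-truth identities.

Each step contributes CI = v̂ · (−r̂) with r̂ evaluated at the step's
*start* point (the difference from midpoint evaluation is O(step/r)).
Steps shorter than half a pixel are flagged invalid and excluded from CI
and speed averages — v̂ is undefined at zero displacement and detection
jitter would otherwise dominate. The primary population statistic pools
all valid steps of all cells (the per-cell mean of means is reported
alongside); net radial displacement per cell is r(first) − r(last),
positive toward the center, averaged over cells. Summaries include all
trajectories with at least one valid step; sensitivity to a minimum
track duration can be probed by filtering the trajectory list before
summarizing.

## Radial gradient

Dye profiles are azimuthal means per radial bin, normalized by the mean
intensity inside 0.8× the inner-reservoir radius at the same time point
(self-normalizing against photobleaching). A per-bin symmetry diagnostic
(coefficient of variation across 8 azimuthal sectors) quantifies how
azimuthally symmetric the signal is. Linearity over a window is a
least-squares line returning slope and R².

The forward model is radial diffusion in the annulus,
∂c/∂t = D(∂²c/∂r² + (1/r)∂c/∂r), with Dirichlet reservoir boundaries
(the ~1.5 mL reservoirs are treated as infinite over ≤ 24 h; in reality
the gradient eventually decays). The solver is a θ-scheme on a uniform
grid (500 points): Crank–Nicolson in the bulk with Rannacher startup
(damped implicit-Euler substeps) to absorb the initial wall
discontinuity, which would otherwise make Crank–Nicolson ring at the
large diffusion numbers involved. Both schemes are unconditionally
stable, so no CFL constraint applies; dt = 0.01 h gives O(dt²) accuracy.
The solution is verified against the closed-form steady state
a + b·ln r (≤ 1e-3 of the span) and obeys the maximum principle. The
default diffusivity, 400 µm²/s, is an illustrative free-dye scale, not a
measured value.

## Synthetic microenvironment generator

The generator provides ground truth for every estimator; its defaults
echo the assay scales: 1 h frame interval, 18 h duration, 70 cells,
mean speed 9.5 µm/h.

*Fiber images*: anti-aliased line segments (default 6000 segments of
60 × 2 µm in a ~2 mm field, a dense collagen-network texture) whose
direction is the prescribed field (radial; vortex = radial rotated by a
fixed in-plane angle; parallel; isotropic) at the segment center plus
von Mises wobble with σ = `wobble_deg`. Wobble maps monotonically onto
measured coherence, which is the property the estimator tests rely on —
the generator's absolute coherence at a given wobble is *not* calibrated
to any particular collagen preparation.

*Cell shapes*: ellipses at log-uniform aspect ratios (default bounds
1–8, area 800 µm²) with protrusive cells modulated by a star-shaped
boundary perturbation (default 6 arms, relative depth 0.35). The
classification margin is verified at generation with the package's own
estimators and the depth escalated if rasterization eroded it, so
generated labels are correct by construction.

*Migration*: a biased persistent random walk. Step directions are drawn
from the product of three directional weights — von Mises persistence
toward the previous direction (concentration p/(1−p) for persistence
weight p ∈ [0,1), so p = 0 is exactly isotropic), von Mises chemotactic
bias toward −r̂ (κ_chemo), and a nematic von Mises guidance term toward
the local fiber axis with doubled angles (κ_guide; both fiber senses
allowed). Multiplying densities (log-linear combination) keeps each
concentration independently interpretable and the all-zero null exactly
isotropic; it is a modeling choice for test generation, not a claim
about cellular mechanism. For a pure chemotactic walk E[CI] =
I₁(κ)/I₀(κ), which `kappa_for_mean_ci` inverts — κ ≈ 0.63 gives
E[CI] = 0.30. Speeds are truncated-normal (mean 9.5, sd 3 µm/h);
directions are sampled on a 720-point angular grid by inverse CDF (bin
width 0.5°, well below every directional scale used). Positions reflect
radially at the seeding-annulus walls (default 600–1500 µm, an explicit
spec field since the walk needs a stated domain); reflected steps near a
wall deviate from the directional law, so deterministic-limit checks
seed away from the walls.

*Rendering*: each cell is drawn as a filled ellipse with its major axis
along its current velocity; the fiber channel is static. A density
warning fires when coverage endangers tracking ground truth.

All generators are seed-reproducible (identical spec + seed →
bit-identical output).

## What the validation shows — and does not

The closed-loop tests (generate with known truth → measure → compare)
verify the estimators' correctness, conventions and tolerances:
orientation recovery within ~1°, coherence monotone in generator
disorder, aspect-ratio recovery within 5% for masks ≥ 300 px, protrusive
labels recovered exactly, ≥ 95% link identity, and pooled CI recovered
within ±0.05 through the full render → segment → link → summarize
pipeline (recovery runs use a 640 px field at 4 µm/px with 70 cells — a
scale at which cell overlap is as rare as in well-plated experiments).
They do not certify performance on real microscopy: the generator has no
uneven illumination, no z-projection blur, no fiber remodeling by cells,
no cell divisions or contacts, and its noise is additive Gaussian rather
than Poisson. Absolute coherence values remain window- and
texture-dependent, and real-data comparisons should sweep
`window_sigma_px`.

## Known limitations

- 2D only: images are analyzed as planar slices; no z-stack
  segmentation or 3D tracking.
- The linker handles moderate densities; it is not a globally optimal
  tracker and will fragment tracks through collisions.
- The diffusion model is single-species with constant D and ignores
  binding/uptake.
- No individual-fiber tracing (lengths, widths, branch points); the
  structure tensor summarizes texture, not fibers.
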