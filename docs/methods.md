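# Methods

`cnscoreg` brings two 3D images of the same central-nervous-system sample —
a low-resolution diffusion-MRI-derived scalar map (e.g. a fractional
anisotropy map at ~125 µm isotropic) and a high-resolution synchrotron X-ray
phase-contrast tomogram (µm scale) — into a single reference frame.  This
note documents the models, the numerical choices, and what the synthetic
validation does and does not show.

## Conventions

All world coordinates are micrometres.  A volume is a 3D array with axes
`(x, y, z)` (z = the cord's long axis), per-axis spacing and a world origin;
the world position of voxel `(i, j, k)` is `origin + (i, j, k) · spacing`.
NIfTI files store millimetres; the conversion happens only at the I/O
boundary.  A spatial transform always maps **fixed-image world coordinates to
moving-image world coordinates** (pull-back resampling).  All randomness is
drawn from seeded `numpy` generators; identical inputs and seeds give
bit-identical outputs, including the phantom volumes and the registration
sampling.

## The two pipeline branches

Brain samples imaged by the two modalities share roughly the same curvature,
so the brain branch is conventional: the tomogram is Gaussian low-passed and
resampled to the MRI grid, both volumes are masked, and the MRI map is
registered to the tomogram by mutual-information affine optimization with an
optional diffeomorphic refinement.

The spinal cord bends differently in each sample holder, and an elongated,
nearly cylindrical object gives a registration metric that is almost
invariant to axial translation.  The cord branch therefore extracts each
modality's cord centerline, resamples both volumes into a straightened
`(u, v, s)` frame (s = arc length along the centerline, u/v = in-plane
offsets), anchors the axial coordinate with two manually placed reference
landmarks, and runs the affine registration in the straightened frame, where
the axial-invariance problem reduces to a well-conditioned 1D shift.  The
registration reference (fixed image) is the straightened high-resolution
volume.  Parametric maps can be carried curved→straight or straight→curved
with trilinear or (for labels) nearest-neighbour interpolation.

## Masking (high-resolution tomograms)

Phase-contrast reconstructions carry alternating bright/dark ring artifacts
at the sample–medium interface, so one threshold cannot separate sample from
medium.  The recipe: (1) *bimodal* threshold — keep voxels **outside** a
medium-intensity band `(low, high)`, which captures tissue plus both ring
polarities; (2) dilation with a discrete Euclidean ball (radius 2 voxels by
default) to close the border; (3) per-slice 2D hole filling (4-connected
background); (4) erosion with the same ball until a single 26-connected
component remains (objective stopping rule for "erode until exterior debris
disappears"); (5) re-dilation by `radius × (1 + n_erosions)` intersected with
the hole-filled pre-dilation support, plus a final per-slice fill, so the
output is one connected, hole-free component that does not overshoot the
sample.

The `auto` band is a two-stage Otsu: the global Otsu threshold `t` is the
upper band edge; a second Otsu restricted to sub-threshold values gives the
lower edge, and is accepted only when it falls **below the sub-threshold
histogram's mode** — otherwise the "dark class" found is just the medium's
own partial-volume tail and the band degenerates to plain Otsu foreground.
Otsu thresholds are computed on a 256-bin histogram and reported as bin
centres; when the between-class variance has a plateau (an empty gap between
modes) the *middle* of the plateau is returned, so thresholding raw values
actually separates the modes (a first-maximizer convention can land inside
the lower mode's bin).

Structuring elements are discrete Euclidean balls throughout; components use
26-connectivity, 2D hole filling uses 4-connected background.  The
low-resolution volume is masked with the same recipe (its auto band
degenerates to plain Otsu when the volume has no dark artifacts) rather than
with an external brain-extraction tool, which keeps the package
self-contained; this is a deliberate substitution.

## Resolution matching

Anti-aliased down-sampling uses a per-axis Gaussian with sigma =
`factor / 2` source voxels (cutoff near the new Nyquist limit) followed by
trilinear resampling; the world position of voxel `(0,0,0)` is preserved.
Nearest-neighbour down-sampling by an integer factor takes exactly every
`factor`-th voxel under the voxel-centre convention, so it creates no new
intensity values.  Intensity saturation clips the top and bottom 0.3 % of
voxel values (nearest-rank quantiles; idempotent).  The NN factor can be
chosen data-driven: the candidate maximizing the mean central-difference
gradient magnitude inside a boundary band on selected xy-slices, ties toward
the smaller factor.  The band is two voxels wide and the gradient is the
plain central difference in intensity per voxel — the operational definition
had to be fixed here since sharpness-at-interface is otherwise ambiguous.

## Centerline extraction

Edges are detected on the (saturated, NN-down-sampled) tomogram by
thresholding the Gaussian-smoothed gradient magnitude twice: strong edges
above the high threshold; weak edges kept only when 26-connected to a strong
voxel (hysteresis).  `auto` sets high = Otsu of the gradient magnitude and
low = 0.4 × high.  Two routes produce the cord geometry:

* **com** — per-slice unweighted centroid of the edge voxels.  Slices whose
  contour count is below half the median per-slice count are skipped: a
  sliver of a contour (the blurred rim of the sample's end face) has a
  meaningless centroid.  The raw polyline is smoothed with a centred
  moving-average (window 5; the window shrinks symmetrically at the ends).
* **grow** — 6-connected seeded region growing of the non-edge space
  (6-connectivity prevents diagonal leakage through one-voxel edge shells),
  closed with a ball of radius 1.  Because internal structure (the
  gray-matter butterfly) partitions the interior into compartments, the
  pipeline grows from several automatically found seeds — local maxima of
  the distance-to-edge transform near the mid-centerline — and unions the
  regions before per-slice hole filling.  An explicit seed can be given
  instead.

The low-resolution volume has no usable edge shell at ~125 µm, so its
centerline comes from per-slice centroids of the Otsu foreground.

## Straightening

Frames along the centerline are rotation-minimizing, built by the
double-reflection method; the initial normal is the world x-axis projected
orthogonal to the first tangent (y-axis fallback when nearly parallel).
Frenet frames were rejected: they are undefined at inflections and twist
violently on near-straight cords.  Tangents are second-order finite
differences of the polyline (first-order end tangents would rotate the
initial frame by O(step) and that error persists along the whole curve).

The transform is injective inside a tube of radius `r` iff `r · κ_max < 1`
(κ_max = maximal discrete curvature); violating configurations are rejected,
never silently folded.  Because voxel-level jitter in an extracted centerline
inflates discrete curvature quadratically in the step, the pipeline resamples
the centerline at a 5-voxel arc-length step before building the transform.
The forward map samples the curved volume at `c(s) + u·n(s) + v·b(s)`; the
inverse projects each curved-world point exactly onto the two polyline
segments adjacent to its nearest centerline sample (the curve model *is*
piecewise linear, so segment projection is the exact local minimizer), then
reads the straight volume there; points beyond the tube radius take the fill
value.  The straight grid is supersampled by default (in-plane spacing and
axial step = half the source voxel): at source spacing the
straighten→unstraighten round trip is limited by the double trilinear
interpolation to ≈ 0.967 correlation on the cord phantom, at half spacing it
reaches ≈ 0.997.

## Registration

**Landmark initialization.**  A similarity transform from two point pairs:
translation of midpoints, the minimal rotation aligning the segment
directions, scale = length ratio (optional).  Two points cannot determine
the roll about the segment axis; it is fixed to 0 and left to the MI
optimization.  In the straightened cord frame the same two landmarks give an
axial shift (+ optional axial scale) via their arc-length positions.

**Metric.**  Mattes mutual information: a Parzen joint histogram with a
zero-order kernel on fixed intensities and a cubic B-spline kernel on moving
intensities, 32 bins, intensities min–max normalized to the bin range.  The
normalization is computed once from the full volumes — a per-sample-set
normalization would let the metric re-scale itself as the transform moves
and bias the optimum.  MI is reported in bits and negated (lower = better).
Fewer than 10 % of fixed samples landing inside the moving image raises a
distinct overlap error rather than returning a (meaningless) value.

**Affine optimization.**  Twelve parameters (3 Euler angles, 3 translations,
3 log-scales, 3 shears; shears frozen by default) about the fixed-image
centre, optimized coarse-to-fine on an anti-aliased pyramid (factors 4/2/1)
by adaptive-step finite-difference gradient descent.  Parameters are scaled
to comparable internal units — translations in voxels; angles, log-scales
and shears in units sized so one step displaces a point at the image
half-extent by about one voxel.  Sampling is full at coarse levels and a
seeded 20 % subset at the finest, with one sampling seed per level so the
metric is a fixed deterministic function while that level is optimized.
Convergence: relative metric improvement < 1e-5 over 10 iterations or step
collapse; a metric that worsens at three successive levels sets a
non-convergence flag and returns the best-so-far transform.

**Diffeomorphic refinement.**  A stationary velocity field driven by demons
forces on z-score-normalized intensities, with Gaussian smoothing of each
update and of the accumulated field, integrated to a displacement by scaling
and squaring (6 steps).  This is a deliberate simplification of full
symmetric normalization with the same contract — smooth and diffeomorphic —
verified post hoc: any field with a non-positive interior Jacobian
determinant is rejected, the smoothing increased once, and failure reported
if it recurs.

## The phantom generator

The phantoms emulate the acquisition geometry the pipeline is built for: a
high-resolution modality rendered in the anatomy frame with an alternating
bright/dark ring artifact at the sample–medium interface, and a
low-resolution modality rendered through the *true* inter-modality transform
(a similarity affine plus an optional parabolic bend of the axial profile,
standing in for holder-induced curvature differences), with separate
intensity level maps per modality.  Rasterization is noiseless and exact
(voxel values are exactly the region levels), with optional seeded Gaussian
noise.  Ground truth is exported: per-modality foreground masks, the
transform, the generating centerline (cord), and two landmark points placed
the way a rater would place them — on the centerline near the extremities
(cord) or at interior off-axis points (brain).

Defaults define the study conditions:

* **cord** — high-res 96×96×160 at 20 µm, low-res 24×24×40 at 80 µm
  (modality ratio 4); tube radius 350 µm; a gentle S-bend (±100 µm) with
  clamped axial end tangents so the tube caps lie flat; a two-lobed
  "butterfly" interior occupying ~55 % of the radius (gray-matter-like);
  ring amplitude 0.5 × tissue level, width 1 voxel ("marginal" artifacts);
  inter-modality transform: 2° rotation, (60, −40, 80) µm translation and a
  150 µm bend — different curvature in the two renderings.
* **brain** — high-res 192³ at 31.25 µm, low-res 48³ at 125 µm; an
  ellipsoidal sample (90 % of the grid) containing a dark "ventricle", a
  bright curved "callosum" band and a "hippocampus" blob, plus a smooth
  plane-wave texture across the whole tissue rendered identically in both
  modalities (FA-like maps vary everywhere; without the texture the MI
  surface is flat under small misalignments).  True transform: 8° rotation,
  500 µm (4 low-res voxels) translation, uniform scale 1.05.

The real acquisitions' resolution ratio between the modalities is ~20:1
(µm-scale tomography against ~125 µm MRI); rendering
that ratio inside a ≤256³ grid would leave a ≤13³ low-resolution grid,
unusable for intensity-based registration, so the phantoms keep reduced
grids at ratio 4–5 — the ratio regime, grid extents and runtimes are chosen
so the full suite runs in minutes on one CPU.

**What the phantoms do not model:** MRI or CT physics (no k-space, no
Fresnel propagation), anatomical realism, partial-volume blur in the
low-resolution rendering (it is point-sampled), susceptibility distortion
beyond a smooth parametric bend, and vasculature.  Passing tests therefore
show the geometric and numerical machinery is correct under known ground
truth — not that the pipeline is robust to every contrast pathology of real
acquisitions.

## Pipeline configuration (YAML)

`cnscoreg run --config cfg.yaml` loads a `PipelineConfig`; all fields with
defaults may be omitted:

```yaml
branch: cord                 # brain | cord
high_path: ph/high.nii.gz    # high-resolution tomogram (NIfTI or TIFF)
low_path: ph/low.nii.gz      # low-resolution scalar map
out_dir: out
high_spacing_um: null        # [x, y, z] µm; required for TIFF inputs
low_spacing_um: null
band: auto                   # masking band, or [low, high]
dilate_radius: 2             # masking ball radius (voxels)
landmarks_high_path: ph/landmarks_high.csv   # cord branch only
landmarks_low_path: ph/landmarks_low.csv
centerline_method: com       # com | grow
straighten_radius_um: null   # default: estimated from the cord cross-section
downsample_candidates: [1, 2, 4]
levels: 3                    # registration pyramid levels
iters_per_level: 120
diffeo: false
seed: 0
```

Referenced paths are checked before any computation; the cord branch refuses
to start without both landmark files.

## Degenerate inputs and failure modes

Constant volumes raise a distinct degenerate-input error from Otsu and the
masking pipeline; erosion that empties the mask before reaching one
component raises an erosion-collapse error naming the last non-empty
iteration; a tube leaving the phantom grid names the first offending
arc-length position; registration initialization without overlap raises an
overlap error rather than a bad metric value; every pipeline failure is
attributable to a named stage in the run log.

## Known limitations

* The affine optimizer is a transparent finite-difference gradient descent;
  it is deterministic and adequate at phantom scale but slower than
  quasi-Newton schemes on large volumes.
* The diffeomorphic refinement is intensity-difference-driven (after
  z-scoring); for strongly non-monotone cross-modality contrast a local
  correlation or MI-gradient force would be needed.
* Roll about the two-landmark axis is unobservable at initialization and
  must be absorbed by the MI optimization; a cord with no internal axial
  asymmetry would leave it undetermined.
* `select_downsample_scale` on an all-constant volume returns the smallest
  candidate (every candidate scores 0); it does not raise.
* Masking is fully automatic; there is no interactive mask editing.  Manual
  fine-tuning of masks is inherently irreproducible, and the recipe's
  parameters (band, radius) are the supported knobs instead.
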