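# Methods

## Problem and scope

Radiostereometric analysis (RSA) measures the rigid-body pose of an object —
a knee implant component or the bone it is fixed to — from a calibrated pair
of simultaneous X-ray projections, with sub-millimetre accuracy. The package
implements a marker-free, automated RSA pipeline with three registration
methods plus the marker-based reference:

- **surface** — silhouette projection of an implant surface mesh, matched to
  the radiographs;
- **volume** — digitally reconstructed radiographs (DRRs) of a synthetic
  volumetric implant model, built by filling the mesh interior with a
  constant value of 3000 on an isometric 0.4 mm voxel grid;
- **bone** — DRRs of a CT-style volumetric bone model, registered with a
  fixed mask that excludes the previously registered implants;
- **marker** — Hough-detected tantalum bead projections, triangulated by
  crossing-line-distance minimization, summarized as the marker centroid and
  matched to a marker-configuration model by least-squares rigid (Kabsch)
  fitting, gated at a mean rigid-body error of 0.35 mm.

A synthetic phantom generates everything a cadaver study would provide, with
exact ground truth, so the whole chain is testable end to end.

## Geometry

The calibration-cage frame is the world frame: the fiducial bead plane is
z = 0, the X-ray sources sit at positive z, units are mm. Each view is a
pin-hole camera: a 3D focal point plus a planar homography from detector
pixel indices (0-based, centers at integers) to fiducial-plane mm.
Calibration estimates the homography from ≥4 fiducial beads (normalized DLT
least squares) and the focal point as the least-squares intersection of the
lines joining each control bead (known 3D position above the plane) to its
observed plane projection. The nominal setup is two sources with a 40°
inter-tube angle and 160 cm source-to-image distance over a uniplanar
detector; beams cross at the specimen, 160 mm above the plane.

Poses are 3×3 rotation matrices plus translations; the optimizer-facing
parameterization is XYZ Euler angles in degrees and translations in mm
around the initial pose, with 1 mm ≡ 1° for simplex steps. Model assets are
centered on their centroid so rotations pivot about the model.

## Rendering

DRRs integrate voxel value × exact intersection length along the ray
through each pixel center, using incremental (Amanatides–Woo) grid
traversal in voxel-index space; the traversal is exact up to floating
point, verified against a dense fine-step ray-sampling oracle. Silhouettes
perspective-project every triangle to the fiducial plane (central
projection maps triangles to triangles) and rasterize the union with the
pixel-center rule.

For similarity *matching*, silhouettes are rasterized on a 4×4 oversampled
grid and block-averaged into fractional pixel coverage. A hard pixel-center
silhouette can only change when a pixel flips, which quantizes the edge
position to whole pixels and left a systematic ~0.1 mm bias at the phantom's
quarter-scale pixels; the partial-coverage rendering is also exactly the
appearance of an opaque part on an area detector. The public silhouette
renderer stays binary.

## Similarity metric and masks

The similarity between an actual radiograph and a virtual projection is the
mean over the horizontal and vertical 3×3 Sobel gradient channels of their
zero-mean normalized cross-correlation (NCC), averaged over the two views.
NCC is invariant to affine intensity rescaling, so no common intensity
calibration is needed. Two masks control the support: a *dynamic* mask (the
initial model projection dilated, default 15 px at the full-scale detector,
scaled with resolution) restricts the local stage to the region of
interest; a *fixed* mask (dilated registered-implant silhouettes, default
5 px) excludes the metal and the surgically removed bone from bone
registration.

Intensity domains, chosen after measuring systematic biases on the phantom:

- Implant matching (silhouette and volume-DRR) operates on the *display*
  image. Radiopaque implants saturate the detector, so their informative
  content is the outline; the implant DRR is tone-mapped
  `1 − exp(−drr/s)` with `s` frozen at 0.01 × the initial pose's DRR
  maximum (the near-opaque limit), which reproduces that appearance.
- Bone matching operates on the *log-attenuation* image
  `−log(1 − display/ceiling)`, the standard linearization of an
  exponential detector response, so the linear bone DRR is compared in its
  native domain.

## Two-stage optimization

Stage one is a controlled random search with local mutations (CRS2-LM,
population 10·(d+1) = 70 by default) over a bounded pose box (±5 mm/±5°
default) on half-resolution images; stage two refines with Nelder–Mead
simplex on full-resolution images with the dynamic mask recomputed once
from the stage-one pose. The best-seen pose is returned, never the last
simplex state, so the final masked objective can never fall below its
starting value. All randomness flows from the config seed; registrations
are bit-reproducible. Implants are registered first; bone registration then
applies the fixed mask at the global stage and fixed ∧ dynamic at the local
stage. Evaluation is restricted to a crop sized from the model's bounding
radius plus the pose bounds and mask radius, which is what makes desk-scale
runtimes possible without changing the objective inside the search box.

## Migration statistics

A displacement series is 5 baseline recordings plus two each at 10, 20, 30,
40, 50, 100, 200, 300, 400, 500, 1000, 2000, 3000, 4000, 5000 µm (35
stereo exams). The measured displacement is the difference between an
exam's estimated position and the coordinate-wise *median* of the five
baselines (robust to one gross outlier). Because the micrometer axes are
never perfectly aligned with the cage axes, the axial direction is fitted
per series as the first principal direction (total-least-squares line
through the origin) of the series' own displacement estimates, signed to
correlate positively with the imposed magnitudes; measured displacements
are the projections onto that axis and errors are measured − imposed.
Accuracy is summarized as grouped mean (SD) with sample SD (n−1), and as
Bland–Altman bias with limits of agreement LOA = bias ± 1.96·SD; the 95%
CIs use SE = SD/√n for the bias and the standard Bland–Altman
SE = SD·√(3/n) for each limit, both with z = 1.96.

The axis fit uses all 30 non-baseline displacement estimates of a series
(the count is configurable); with five baselines and fifteen doubled steps
there is no 25-displacement subset that is obviously preferable.

## Synthetic phantom

The phantom emulates the study conditions rather than any particular
anatomy:

- **Detector**: quarter-scale by default (552 × 667 px at 0.64 mm instead
  of 2208 × 2668 at 0.16 mm) for desk-scale runtimes; the geometry
  (magnifications, 40° tube angle, 1600 mm source-to-image distance) is
  unchanged and the full-scale detector is one parameter away.
- **Implant**: an asymmetric tray (extruded heptagon, 10 mm thick) with an
  offset keel and a distant peg, so all six pose parameters move the
  silhouette. The solid is tilted 8/5/12° inside its local frame so no flat
  face is aligned with the voxel grid — grid-aligned faces voxelize with a
  coherent sub-voxel phase offset instead of an unbiased dithered boundary.
  The registered synthetic volume uses the standard 0.4 mm spacing.
- **Bone**: tapered cortical shell (value 1200) around a smoothly textured
  trabecular interior (mean 300, SD 120), 100 mm long at 1.5 mm voxels,
  with the bone inside the implant's dilated bounding box resected.
- **Beads**: ten 1.0 mm tantalum-like beads placed wide-spread inside the
  remaining bone, ≥10 mm apart.
- **Detector model**: an inverted-exposure radiograph,
  `display = S·(1 − T_tissue·T_metal)` with exponential tissue
  transmission (scale 60000) and the implant treated as opaque: `T_metal`
  is the unblocked fraction of each pixel from 4×4-supersampled coverage of
  the exact mesh silhouette. Implant alloys attenuate orders of magnitude
  more than bone, so partial transmission through metal is negligible at
  diagnostic energies.
- **Noise**: Gaussian read noise (SD 800 display units) plus a
  signal-scaled term with SD = signal/photon_scale (default 50), set to
  give bead contrast-to-noise near 20. Bead projections are rendered
  analytically (exact sphere chord lengths), so their ground-truth image
  positions are known to machine precision.
- **Protocol**: series displace the whole specimen along a micrometer axis
  tilted 1.5° from the nominal cage axis, emulating the imperfect fixture
  alignment that makes the per-series axis fit necessary. Study exams also
  reposition the specimen by ±2 mm/±3° between recordings, as re-setups
  between series would.

What the phantom does **not** emulate: anatomical bone shape, scatter,
beam hardening, detector blur beyond the implant-edge coverage model,
implant CT artifacts, or soft tissue. Passing tests therefore demonstrate
the internal consistency and statistical behavior of the chain under
controlled imaging physics, not clinical accuracy.

## Numerical choices and edge cases

- Point-in-polyhedron uses signed ray parity (Möller–Trumbore) with a
  shared pseudo-random ray direction and jittered retries for rays that
  graze edges, vertices or the surface; verified exact against a convex
  hull oracle.
- Homography fitting refuses <4 or collinear correspondences; focal-point
  estimation refuses near-parallel line bundles; triangulation refuses
  near-parallel rays; rigid fitting refuses <3 or collinear markers and
  enforces det = +1 (a reflection produces large residuals and fails the
  0.35 mm gate rather than being silently accepted).
- Degenerate poses inside the search box (empty or constant masked region)
  score −1 rather than raising, so the global stage can traverse them.
- A perfectly flat local objective is flagged as non-convergence and the
  start pose is returned.
- Bead detection validates Hough candidates by disc-vs-annulus contrast
  against a robust (MAD) noise scale, rejecting circles hallucinated from
  noise; centers are refined by intensity-weighted centroids.

## Known limitations

- Translational accuracy is the validated quantity, as in the underlying
  experimental design; rotations are estimated but plate-like implants
  leave ~0.5° of rotational play that the tests do not gate.
- The volume method's binary 0.4 mm synthetic model differs from the
  continuous truth by up to half a voxel; its zero-noise self-consistency
  floor is ~0.1 mm at quarter scale, visibly worse than the surface
  (exact) and bone (~0.006 mm) methods. This mirrors the method's standing
  relative to the silhouette method in practice.
- Problem sizes in the test suite (quarter-scale detector, 8–20 exams per
  study, compact optimizer budgets) are the package's chosen desk-scale
  study conditions; they are stated in each test.
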