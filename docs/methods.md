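# Methods

## Overview

`liverphantom` synthesizes a 4-D (3-D + respiratory phase) abdominal MR
phantom with a moving, textured liver and an embedded spherical tumor.  The
pipeline has four stages:

1. **Reference anatomy** — a labeled voxel volume at end of exhalation (EOE)
   on a 256×256×150 grid with isotropic 1.6719 mm voxels;
2. **Reference appearance** — a T1-like intensity volume composited per
   tissue category, with the tumor inserted last;
3. **Motion** — a per-structure forward displacement model scaled through a
   respiratory motion–time curve, numerically inverted to backward fields
   that pull the reference through all 10 phases of a 5 s cycle;
4. **Measurement** — algorithmic tumor segmentation, volume and
   center-of-mass (COM) kinematics per phase.

Axes follow the anatomical convention +x left, +y anterior, +z superior, so
superior–inferior (SI) motion is along z and anterior–posterior (AP) motion
along y.  All working grids share one physical field of view
(~428×428×251 mm); coarser grids scale the spacing, never the anatomy, so
organ volumes, the 15 mm tumor radius and motion amplitudes keep their
physical meaning at every resolution.

## Reference anatomy

Organs are geometric primitives (superellipsoids, capsules, extruded
superellipse bands) laid out plausibly: lungs superior, liver right-superior
carving a diaphragm dome into the right lung, heart on the diaphragm
carving the left lung, spine/cord/static-marrow as a posterior midline
cylinder complex, kidneys posterior-inferior tucked under the liver,
intestine inferior with an air core, muscle as a deep annular band and
"body" as everything else inside the trunk.  Overlap is resolved by painting
in ascending precedence (body < soft tissue < air spaces < bone <
category I organs), which makes the label image a partition by construction.

The liver primitive is isotropically rescaled about its center (bisection on
a signed-distance rasterization) until the painted, post-carve mask hits the
reference volume of **1975.90 mL** within 0.05 mL (one voxel is
0.0047 mL at native resolution, so the tolerance is attainable; on coarser
grids it is floored at one voxel volume).

The tumor is a sphere of radius 15 mm placed on the liver's vertical
(centroid) axis 30 mm below the superior pole.  Placement enforces a 12 mm
clearance between the tumor surface and the liver boundary via the liver's
Euclidean distance transform.

## Structure table and intensity model

Each structure carries a category (I–IV), a base intensity `A`, optionally a
detail mean `B`, and motion fractions (κ_si, κ_ap).  The shipped table
(`data/structures.yaml`) lists, e.g., liver A=95/B=160, spleen 25/170,
muscle 40/140, lungs 18, spine 38.  Composited organ means are `A + B`
(liver ≈ 255 before tumor insertion).

* **Category I** (liver, gallbladder, pancreas, spleen, stomach, kidneys,
  heart = pericardium + myocardium + heart blood): a donor organ texture is
  deformably mapped onto the phantom mask with the mask-driven Demons
  registration (below), uncovered mask voxels are filled from their nearest
  covered neighbor, the detail is rescaled *multiplicatively* to mean `B`
  (pure scaling preserves zero and relative contrast), and added to `A`.
* **Category II** (muscle, body, static marrow, intestine wall): iterative
  patch transplantation from the donor muscle block — random unassigned 5³
  sites receive random donor 5³ blocks until none fit (verified by an
  exhaustive sliding-window scan after 200 consecutive rejections), then 3³,
  then single voxels, so each voxel is assigned exactly once; a
  mask-restricted normalized 5³ moving average then smooths the result.
* **Category III** (lungs, airway, intestinal air, esophagus wall, ambient
  air): uniform `A`; lungs and intestinal air get additive Rayleigh noise
  with sample mean 5 (scale σ = 5·√(2/π), variance (2−π/2)σ² ≈ 6.83).
* **Category IV** (bone): placeholder muscle/body texture in the reference
  (host chosen by majority label in a 2-voxel dilation shell); every phase
  re-renders bone voxels with their uniform `A` from the warped labels, and
  the reference static-marrow texture is re-inserted unchanged.

**Tumor.** The radial profile is the quartic Δ(ρ) = Δ₀(1−(ρ/r)²)² with
Δ₀ = 100, which vanishes with zero slope at the rim.  Inside the sphere the
texture is blended toward the local liver mean (mean over liver voxels in a
30 mm ball) with the same quartic weight before the depression is
subtracted, so the center intensity is *exactly* `local mean − 100` while
the rim joins the untouched texture smoothly.

**Synthetic donor.** The donor "scan" is a jittered copy of the parametric
anatomy (semi-axes ±6 %, centers ±5 mm, seeded) carrying a
Gaussian-correlated random field (mean 100, sd 15, correlation length 4 mm,
clipped at 0) with dark tubular vessel tracks inside the donor liver.  The
donor muscle block is a 48 mm cube of the same texture process.  What this
emulates: organ-scale shape variation between patient and phantom, T1-like
soft-tissue texture statistics, hepatic vessels.  What it does not: coil
bias fields, acquisition noise correlations, sequence-dependent contrast,
true hepatic lobular anatomy — so passing tests demonstrate pipeline
correctness and calibration, not radiological realism of any single image.

## Respiratory motion

The motion–time curve m(t) is a continuous, periodic, asymmetric
squared-sinusoid over the 5 s cycle: m = sin²(πt/4) while inhaling
(0 ≤ t < 2 s), m = cos²(π(t−2)/6) while exhaling, with m(0)=0 (EOE,
reference) and m(2)=1 (EOI).  The analytic form is a stand-in chosen to
match the stated EOE/EOI timing; only its anchor values and smoothness
matter downstream.  Presets set the maximum diaphragm/chest amplitudes:
large 3.0/2.0 cm, normal 2.0/1.2 cm, limited 2.0/0.5 cm.

### Forward field synthesis

Each structure moves rigidly by (0, +κ_ap·A_ap·m, −κ_si·A_d·m).  The liver
fractions are calibrated so the normal-preset EOE→EOI excursion is 19.2 mm
SI and 11.0 mm AP (κ_si = 0.96, κ_ap = 11/12); other fractions are
physiologic defaults (heart 0.70, intestine 0.55, kidneys 0.75, body 0.35
SI, …), are table-driven and overridable, and carry no calibration burden.
The anterior chest-wall shell (outermost 15 mm of the anterior body half,
including the chest-wall bones embedded in it) carries the full AP
amplitude; the posterior spine complex is pinned to zero.

The piecewise-constant field is blended by **Dirichlet relaxation**: the
exact rigid vectors are held fixed ("pinned") inside each category-I organ
mask eroded by 6 mm (floored at 2 voxels on coarse grids), in the spine
complex and in the outer chest-wall shell, while repeated Gaussian diffusion
passes (100 on a 4× coarse grid, then 12 fine passes, σ = 1 voxel) drive the
free region toward the harmonic interpolation of the pinned values.  The
max principle then keeps transition gradients as gentle as the core
geometry allows, which is what makes the forward map diffeomorphic at the
preset amplitudes.  Two geometric safeguards: organ cores are
morphologically opened (sharp organ poles would anchor steep gradients), and
where another organ's core would sit against the liver's, the softer organ
yields (its core is released in the contact zone).  Ambient air rides the
nearest body-surface motion with a 30 mm exponential decay (then relaxed
with the body pinned), so the expanding chest pushes into co-moving air
rather than folding the field at the skin.

Because every contribution scales with m(t), the unit field is built once
per preset and each phase only rescales it.

### Inversion, repair, warping

Backward fields solve u_b(x) = −u_f(x + u_b(x)) by fixed-point iteration
(≤ 50 iterations, stop when the max update < 0.01 voxel).  The composition
residual ‖u_f(x+u_b)+u_b‖∞ over in-grid pullbacks must be ≤ 0.05 voxel;
voxels the plain iteration leaves above half that tolerance (it stalls where
the forward Jacobian's spectral radius nears 1, even though the map is
invertible) get a vectorized per-voxel Newton polish on the same equation.
Exceeding the tolerance raises an error rather than returning a bad field.
At the large preset a handful of voxels at organ-contact corners remain
marginally non-diffeomorphic (det(I+∇u) slightly < 0 pointwise at
half-resolution); the residual criterion is still met at voxel sampling,
and this is a known limitation of the piecewise-rigid model at 3 cm
amplitude.

The morphological DVF repair flags voxels whose component deviates from the
3³ neighborhood median by > 2 mm while ≥ 20 of the 26 neighbors agree with
that median within 0.5 mm (isolated holes/spurs, not coherent clusters),
replaces them with the median, and sweeps at most twice.  The synthetic
fields are clean, so this pass is normally a no-op; it exists for ingested
fields and is verified by inject-and-repair tests.

Intensities are pulled with interpolating cubic B-splines (exact at grid
nodes; out-of-grid pullbacks filled with the ambient-air intensity 40);
labels with nearest neighbor.

### Per-phase assembly

forward → repair → invert → warp volume + labels → re-render category IV
uniform intensities from the warped labels → re-insert the reference
static-marrow texture → 3³ moving average on the one-voxel
dilation/erosion shell of the spine complex (fuses the spine/marrow
surface) → center-weighted smoothing everywhere else.  The weighted kernel
is the 5³ truncated Gaussian with σ = 1.25 voxels *of the native grid*
(2.09 mm, ±3.3 mm window); holding its physical scale fixed keeps coarser
working grids from over-smoothing the 15 mm tumor — on the native grid it
is exactly the 5³ kernel.  Phase 1 (t = 0, zero field) skips the warp but
receives the same post-processing, so all 10 phases are homogeneous.

## Demons registration

Binary masks are registered as Gaussian-smoothed indicators (σ equal to
2 voxels of the native grid, in mm) with the classic force
`du = diff·∇M∘φ / (|∇M∘φ|² + diff² + ε)`, per-iteration fluid smoothing of
the update and diffusion smoothing of the field, update step capped at
2 voxels, over a 4×/2×/1× pyramid with 100/50/25 iterations.  All smoothing
scales are physical (mm) with a one-voxel floor, so behavior is consistent
from the native grid down to demo grids.  A final Dice < 0.90 raises a
warning from the registration and an error from the texture-mapping caller.

## Tumor measurement

Within a 30 mm search ball at the tumor's nominal phase position, the liver
background is the median intensity of the ball's outer 5 mm shell; voxels
depressed below it by more than Δ₀/2 = 50 form the candidate set and the
largest connected component is the tumor.  On the noiseless quartic this
selects radius r·√(1−2^(−1/2)) ≈ 8.12 mm (≈ 2.24 cm³) — intentionally a
smaller core than the full sphere, so volume *stability* across phases and
COM *excursions* are the meaningful outputs, not the absolute volume.
Series measurements evaluate the same rule on a 2× trilinearly supersampled
lattice (`segment_tumor_fine`): one half-resolution voxel is 0.037 cm³, and
plain counting would quantize the per-phase volume more coarsely than the
physics being measured; sub-voxel evaluation is the analogue of contouring
on interpolated display slices.  No pre-smoothing is applied before
thresholding: a slope/noise computation on the smoothed noiseless profile
shows extra smoothing flattens the 50-contour faster than it suppresses the
4 mm-correlated texture noise.

## Problem sizes and numerical defaults

* Native grid 256×256×150 (1.6719 mm): liver calibration, Rayleigh noise
  check, tumor kinematics (phases P1 and P5 only).
* Half-resolution 128×128×75 (3.3438 mm): the full 10-phase series for
  volume stability, the category-I mapping quality, and the liver-inflation
  workflow (reference 1975.90 mL → enlarged 2200.00 mL concentric spheres
  on a cropped cube).
* Demo grid 64×64×38 (6.6876 mm): `make-demo` CI runs; same physical
  anatomy, coarse sampling.

Key tolerances: calibration 0.05 mL (≥ 1 voxel), inversion residual
0.05 voxel, registration Dice floor 0.90, pattern rejection cutoff 200
consecutive draws before the exhaustive scan.  All randomness flows from a
single integer seed through named substreams (donor texture, per-SOI
patterns, noise), so a fixed seed reproduces every volume bit-for-bit.

## Known limitations

* Organ geometry is schematic; shapes carry no anatomical fidelity beyond
  topology, laterality and calibrated liver volume.  Real label/texture
  volumes can be substituted through the ingest interfaces.
* Motion is piecewise-rigid with harmonic blending: no hysteresis (inhale
  and exhale trace the same spatial field), no tissue incompressibility
  constraint, no biomechanical contact model; the large preset is at the
  edge of what the model renders diffeomorphically.
* MR physics is not simulated: intensities are target means with texture,
  not signal equations; noise is additive Rayleigh in the air spaces only.
* The tumor moves with the liver; desynchronized or irregular trajectories
  are an explicit hook (per-structure κ override), not a default feature.
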