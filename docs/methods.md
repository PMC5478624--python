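# Methods

## Problem and approach

A freshly prepared seedbed is a near-planar soil surface strewn with
aggregates ("clods") whose size distribution — the tilth — strongly affects
seed–soil contact, emergence and early growth. `seedbed3d` characterizes
that surface from a single nadir frame of a consumer structured-light depth
camera (Kinect-class: 640×480 range map in mm, mounted ~0.8 m above the
soil, optical axis vertical) and condenses it into areal texture parameters
and a tilth grade.

The processing chain is:

1. **Reconstruction.** Every valid pixel (range > 0) is back-projected with
   the pinhole model `X = (x′−cx)·depth/fx`, `Y = (y′−cy)·depth/fy`,
   `Z = depth`; the cloud is rasterized to a regular metric height grid
   (`h = camera_height − Z`, so clods are positive bumps). Cells containing
   no point are marked invalid and excluded from every statistic. A
   Delaunay triangulation over (X, Y) provides a surface mesh for export
   only; all statistics are computed on the raster.
2. **Form removal.** A least-squares plane is fitted to the valid cells and
   subtracted (the areal analogue of the ISO form operation). Without this,
   camera tilt or field slope would leak into every height parameter.
3. **Decomposition.** The detrended surface G(r) is split into a basal
   ground form and a block residual, `G = G_basal + G_block`, where
   `G_basal` is a Gaussian low-pass of the surface and `G_block` the exact
   cell-wise difference; the reconstruction identity holds to machine
   precision by construction.
4. **Clod inventory.** The block residual is thresholded, labelled
   (8-connectivity, minimum footprint 4 cells to suppress depth-noise
   speckle) and each component measured: footprint area, major/minor
   extents, maximum residual height, and area-equivalent diameter
   `d = 2√(area/π)`, which is then binned into the tilth size classes
   (<5, 5–15, 15–50, 50–80, 80–120, >120 mm; half-open `[low, high)`).
5. **Texture parameters.** On the detrended field with valid area A:
   `Sa = (1/A)∬|z|`, `Sq = √((1/A)∬z²)`, `Ssk = (1/Sq³)(1/A)∬z³`,
   `Sku = (1/Sq⁴)(1/A)∬z⁴`. Integrals are cell sums × cell area with
   invalid cells excluded from both numerator and A, making each parameter
   a plain moment of the valid-cell height sample. Sku is the raw fourth
   standardized moment (Gaussian surface → 3).
6. **Grading.** The plot is assigned the nearest of 10 reference grades in
   standardized (Sa, Sq) space. The packaged reference tables give, per
   grade, the sieved size-class composition and characteristic Sa, Sq, Ssk,
   Sku (Sa and Sq in mm, strictly increasing with grade). Only Sa and Sq
   enter the classifier because Ssk/Sku do not discriminate the grades;
   ties break toward the lower grade.
7. **Validation statistics.** Agreement between sensor-derived and manual
   (pin-meter) values is scored with R² (squared Pearson correlation — the
   quantity read off a 1:1 scatter; an `sse` variant `1 − SSE/SST` is
   available), `RMSE`, and `REP = 100·RMSE/mean(reference)` (percent), per
   parameter × grade group (1–3 / 4–6 / 7–10) × dataset, under a seeded
   50/50 calibration/validation split stratified by grade.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fx, fy, cx, cy` | 585.6, 585.6, 316, 247.6 px | depth-camera intrinsics (typical Kinect-v1 calibration), used when a frame has no sidecar |
| `camera_height_mm` | 800 | sensor height above the ground reference |
| `grid_pitch_mm` | ground-sample distance (`camera_height/fx` ≈ 1.37 mm) | rasterization cell size; at nadir this is nearly lossless |
| `sigma_frac` | 0.05 | basal filter scale as a fraction of image width (σ = 32 px on a 640-px frame); a form filter must span many clods, so the scale is tied to the frame, not the pixel |
| `threshold_method` | `otsu` | block binarization; `triangle` recovers thin rims better on low-noise residuals but chases speckle on noisy frames; `fixed` takes a value in mm |
| `min_area_cells` | 4 | smallest clod footprint kept |

Holes (range 0) are masked, never inpainted; masking keeps the moments
unbiased, whereas inpainting would invent surface.

## The synthetic seedbed generator

Field data cannot ship with the package, so a simulator provides graded
scenes with exact ground truth:

- **Composition sampling.** A clod diameter is drawn by choosing a size
  class with the grade's composition probabilities, then uniformly within
  the class, truncated to [1 mm, max grain size of the grade]. Fractions
  are treated as count fractions.
- **Placement.** Clods are spherical caps (height = 0.4 × diameter) placed
  uniformly at random and combined by maximum, so overlapping clods rest on
  one another. Clods are added until their summed footprint reaches a
  target coverage of the plot (default 0.8), emulating sieved soil spread
  over the plot at roughly constant areal density; an explicit clod count
  can be forced instead. The plot (920 × 700 mm) slightly exceeds the
  camera footprint at 0.8 m so the frame never sees past its edge. Because
  higher grades are built from larger aggregates, mean Sa/Sq of the
  generated surfaces increases strictly with grade.
- **Rendering.** Per-pixel range is found by intersecting the pixel ray
  with the surface (two fixed-point refinements, ample for relief far
  shallower than the camera height), then corrupted with additive Gaussian
  noise (σ = 1.5 mm), quantization (2 mm, the structured-light depth
  resolution near 0.8 m) and random dropout holes (2 %), the artefact
  strong sunlight produces in the field. All randomness flows from explicit
  seeds; identical seeds give identical scenes bit for bit.

What the simulator does **not** emulate: irregular (non-convex, angular)
clod shapes, inter-clod porosity and shadowing, surface moisture/specular
dropout patterns (holes here are i.i.d.), multi-path range artefacts, and
the absolute Sa/Sq magnitudes of real graded field plots (real coarse
seedbeds are rougher than a plane strewn with caps, since clods stack into
ridges). Passing round-trip tests therefore demonstrates the correctness
and monotone sensitivity of the measurement chain, not field accuracy of
any particular sensor.

## Numerical choices

- Basal filtering uses normalized (mask-aware) convolution with reflect
  borders: invalid cells neither bleed zeros into the estimate nor darken
  the border.
- The Laplacian-of-Gaussian blob response subtracts the valid-cell mean
  before filtering because the truncated discrete derivative kernel is not
  exactly zero-sum; without centring, a constant field would yield a small
  constant response.
- `texture_parameters` re-centres the detrended heights and flags Ssk/Sku
  as NaN when Sq < 1e-9 mm: below that the "relief" is floating-point
  cancellation noise from the plane fit and the standardized moments are
  meaningless. The scalar `compute_ssk`/`compute_sku` raise instead, for
  callers who want the error.
- Degenerate thin regions can report a zero minor ellipse axis; clod
  extents are floored at one cell so `length ≥ width > 0` always holds.
- Ties in grade classification (exact midpoints) resolve to the lower
  grade via a stable argmin over grade order.
- The calibration/validation split draws per-stratum permutations from a
  single seeded generator; strata with fewer than 2 records fall back to an
  unstratified draw.

## Verification problem sizes

The test suite verifies the moment computations against an independent
brute-force double-loop oracle on 16×16 grids (agreement to 1e-12
relative), closed forms on sinusoidal and two-level surfaces, Gaussian
surfaces at 10⁵ cells, sampler fidelity at 10⁵ draws per grade, and the
full render-and-measure loop on 10 grades × 5 seeds at the native 640×480
frame size. With those scene sizes the recovered mean Sa rises strictly
from grade 1 to 10 and matches ground truth within a few percent for
grades ≥ 4; for the finest grades the 2-mm depth quantization dominates the
sub-millimetre relief and recovery saturates at the noise floor — the same
resolution limit any structured-light sensor shows on fine tilth.

## Known limitations

- Single-frame only: no multi-view registration or fusion; occluded clod
  flanks are unobserved, so clod heights are measured from the visible
  residual.
- Touching clods are not split (no watershed); the inventory undercounts
  in dense scenes and the size distribution shifts coarse.
- Grade classification assumes the reference table's Sa/Sq scale; sensors
  or surfaces outside that calibration need their own reference rows.
- The emergence-speed summary operationalizes "speed" as threshold-crossing
  days of the cumulative curve; it does not fit a germination model.
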