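# seedbed3d

Quantify the 3D structure of a cultivated seedbed from a single consumer
depth-camera frame.

After tillage, a seedbed is a roughly planar soil surface covered with
aggregates (clods). How coarse that surface is — the *tilth* — governs
seed–soil contact and crop emergence, but it is traditionally scored by
sieving soil samples or eyeballing the plot. `seedbed3d` replaces that with
a non-contact measurement: a nadir depth frame (Kinect-class
structured-light sensor, 640×480 range map in mm, ~0.8 m above the soil) is
turned into a metric surface model, decomposed into ground form plus clods,
and summarized as standard areal texture parameters and a 10-grade tilth
classification.

## The model

With pinhole intrinsics (fx, fy, cx, cy), each valid pixel (x′, y′) with
range *d* (mm) back-projects to

    X = (x′ − cx) · d / fx,   Y = (y′ − cy) · d / fy,   Z = d

and the height above ground is `h = camera_height − Z`. After least-squares
plane removal, the surface G(**r**) is split into a basal ground form and a
block (clod) component,

    G(r) = G_basal(r) + G_block(r)

where `G_basal` is a Gaussian low-pass (σ = 0.05 of the image width) and
`G_block` the exact residual. Clods are segmented from `G_block`
(Otsu threshold, 8-connected labelling) and measured; each gets an
area-equivalent diameter `d = 2√(area/π)` binned into the classes
<5, 5–15, 15–50, 50–80, 80–120, >120 mm. On the detrended heights z over
valid area A the areal texture parameters are

    Sa  = (1/A) ∬ |z| dA                  mean absolute height
    Sq  = √( (1/A) ∬ z² dA )              RMS height
    Ssk = (1/Sq³) (1/A) ∬ z³ dA           skewness
    Sku = (1/Sq⁴) (1/A) ∬ z⁴ dA           kurtosis (Gaussian → 3)

and the plot is assigned the nearest of 10 reference tilth grades in
standardized (Sa, Sq) space. Agreement with manual (pin-meter) profiles is
scored with R², RMSE and REP = 100·RMSE/mean under a seeded, stratified
50/50 calibration/validation split. A deterministic seedbed simulator
(grade-conditioned clod sampling, spherical-cap placement, ray-cast
rendering with sensor noise) provides ground-truthed scenes for testing and
demos. Full details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a mid-coarseness scene, then run the full measurement chain on the
rendered depth frame:

```bash
$ seedbed3d simulate --grade 6 --seed 11 --out demo/plot
grade 6 scene (seed 11): 858 clods, true Sa=7.12 mm -> demo/plot.png

$ seedbed3d texture demo/plot.png
plot: Sa=6.93 mm  Sq=7.90 mm  Ssk=0.68  Sku=2.12  grade=3

$ seedbed3d blocks demo/plot.png --out demo/out
plot: 144 clods -> demo/out/plot_blocks.csv

$ head -2 demo/out/plot_blocks.csv
label,area_mm2,length_mm,width_mm,height_mm,equiv_diameter_mm,centroid_x_mm,centroid_y_mm
1,18.66,9.85,3.09,5.04,4.87,571.31,4.51
```

The recovered Sa (6.93 mm) tracks the scene's ground truth (7.12 mm)
through rendering, sensor noise and the full pipeline. The grade readout is
on the reference-table scale, which is calibrated to real field plots;
synthetic cap-built surfaces are smoother than real soil of the same
composition, so a simulated grade-6 scene reads as a lower grade — the
simulator is a test harness for the measurement chain, not a stand-in for
field calibration (see docs/methods.md).

Other subcommands: `reconstruct` (depth → PLY point cloud or mesh),
`grade`, and `validate` (sensor vs. manual CSVs → 12-row R²/RMSE/REP
report). The same pipeline is available from Python:

```python
from seedbed3d import PipelineConfig, build_seedbed, render_depth, analyze_depth_image

scene = build_seedbed(grade=6, seed=11)
image = render_depth(scene, seed=11)
report = analyze_depth_image(image, PipelineConfig())
print(report.texture.sa, report.grade, len(report.blocks))
```

Depth frames are 16-bit PNGs (value = range in mm, 0 = hole) with an
optional JSON/YAML intrinsics sidecar; without one, a typical Kinect-v1
calibration (fx = fy = 585.6, cx = 316, cy = 247.6, 800 mm height) is
assumed.

## Layout

```
src/seedbed3d/
  camera.py     pinhole model, depth frames, point clouds, rasterization
  surface.py    height fields, plane fit, Gaussian decomposition, meshing
  roughness.py  Sa/Sq/Ssk/Sku areal texture parameters
  blocks.py     clod segmentation, measurement, size distribution
  grading.py    reference tables, grade classifier, R²/RMSE/REP validation
  agronomy.py   emergence rate and speed summaries
  simulate.py   graded seedbed generator and depth rendering
  io.py         PNG depth frames, sidecars, PLY, decomposition export
  pipeline.py   end-to-end per-plot analysis and validation runs
  cli.py        `seedbed3d` command-line interface
  data/         grade composition and texture reference tables (CSV)
```
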