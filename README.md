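# gantryvision

A fully software-simulated re-creation of an automated plant-imaging rig:
a gantry-mounted pan-tilt camera that photographs small plants at marked
floor positions against a blue keying background, and labels every plant in
every image with a bounding box computed **purely from known geometry** —
no detector, no manual annotation. The package is aimed at people building
labeled plant-image datasets for machine-learning work in agriculture, and
at anyone who wants to study or extend the geometric auto-labeling idea
without access to the physical hardware.

## What it implements

**Geometry.** The transform chain `T = T_w2c · T_c2i`: a rigid world→camera
transform (translation to the optical center, then pan and tilt rotations)
followed by a rectilinear (pinhole) camera→image projection with focal
length derived from the diagonal field of view (default 4000×3000 px,
98.7°). A plant at world position **p** is replaced by a bounding sphere of
radius *R*; at camera distance *D* the sphere subtends the half-angle
asin(*R*/*D*), and projecting the extreme rays of the silhouette cone
(closed form, per image axis) yields a fractional bounding box guaranteed
to contain the whole plant. Because plants sit on the floor (*z* known),
the chain inverts exactly: any image point back-projects along its ray to a
unique ground-plane point.

**Planning and timing.** Axis speed follows the stepper-drive chain
`v = p_r · d · s · r · m` (*d* = 105 mm/rev, *s* = 1.8/360, *r* = 0.2,
*m* = 1 or 0.5 for full/half stepping — 0.105 mm/pulse), camera positions
are visited in a nested zig-zag through slabs and columns of the travel
volume, and each leg is timed with a trapezoidal/triangular velocity
profile (`D/p_r + p_r/a`, or `2·√(D/a)` for short moves). Production rates
are `t_m = (t_p + t_d)/N_m` and `t_s = (t_p + t_d + t_c)/N_s`.

**Scenes and segmentation.** A seeded scene generator places parametric
rosette sprites at marked floor positions and renders master images by
exact inverse ray casting, producing per-pixel ground-truth masks. Chroma
keying thresholds the CIELAB *b* (blue–yellow) channel, with morphological
cleanup, background replacement and pose-matched background subtraction.

**Labeling and statistics.** Subimages are cropped from the projected
boxes and described by v1.5 JSON metadata records (schema-validated);
evaluation statistics cover accuracy, binomial standard error
`√(p(1−p)/n)`, exact Clopper–Pearson intervals and class weights
`c = total/class count`.

## Worked example

```python
from gantryvision import (CameraModel, CameraPose, WorldPoint, BoundingSphere,
                          project_sphere, world_to_camera, camera_to_image)
from gantryvision.geometry import aim_at

model = CameraModel()                      # 4000x3000 px, 98.7 deg diagonal
plant = WorldPoint(575, 420, 0)            # marked floor position, mm
pose  = aim_at(WorldPoint(775, 420, 500), plant)
box   = project_sphere(pose, model, BoundingSphere(plant, 90.0))
print(f"pan={pose.pan:.1f} tilt={pose.tilt:.1f}")
print(f"box x=[{box.x_min:.3f},{box.x_max:.3f}] y=[{box.y_min:.3f},{box.y_max:.3f}]")
```

prints

```
pan=180.0 tilt=68.2
box x=[0.409,0.591] y=[0.379,0.621]
```

The camera 200 mm east and 500 mm above the plant aims back at it
(pan 180°, tilted 68.2° below the horizontal); the 90 mm bounding sphere
projects to a box roughly centered in the frame covering ~18% of the image
width. Every rendered pixel of that plant is guaranteed to fall inside the
box — that is the property the whole labeling pipeline rests on.

A complete simulated production run (scene → route → capture → label):

```bash
gantryvision run --out myrun --seed 1 --fixed-clock
gantryvision summarize myrun
```

which reports, for the default 9 locations × 4 viewpoints:

```
Masters	36
Subimages	186
Imaging time t_p (s)	262.3
t_m (s/master)	8.57
t_s (s/subimage)	2.24
```

plus per-species subimage counts. Timing constants (3 s settling pause,
2.7 s capture) and motion settings (3000 pulses/s, half-steps) mirror a
conservative daily production setup.

## Layout

- `src/gantryvision/geometry.py` — transform chain, sphere boxes, pose sets
- `src/gantryvision/planner.py` — speeds, zig-zag routing, schedule, rates
- `src/gantryvision/scene.py` — synthetic scenes and ground-truth rendering
- `src/gantryvision/segmentation.py` — CIELAB keying and background tools
- `src/gantryvision/labeler.py` — cropping, v1.5 metadata, organization
- `src/gantryvision/stats.py` — evaluation and dataset statistics
- `src/gantryvision/pipeline.py`, `cli.py` — end-to-end runs and the CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
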