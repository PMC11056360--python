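# brimplan

Extra-articular screw-placement planning on the pelvic brim for the Stoppa
(anterior intrapelvic) approach.

Reconstruction plates for pelvic and acetabular fractures are laid along the
pelvic brim, but the hip joint surface cannot be seen through the Stoppa
window, so a drilled screw can silently enter the acetabular socket.
`brimplan` is a small library + CLI for surgeons' planning workflows and for
morphometric studies of this problem. It measures a hemi-pelvis model
(brim polyline, acetabular rim, body axis) and computes where along the brim
drilling is safe.

The core constructions, with arc positions measured along the brim from the
sacroiliac joint (**C**) to the pubic symphysis (**D**):

* **Point A**: intersection of the brim with the transverse plane through
  the superior acetabular margin.
* **Point B**: the brim is fitted as a portion of a circle; B is where the
  ray from the circle center through the inferior acetabular margin meets
  the brim.
* Zones **a** (C→A) and **c** (B→D) are safe; zone **b** (A→B) overlies the
  socket and is dangerous.
* With plate hole spacing *d* and vacant-hole spans *e_n*, the safe screw
  count per zone is the largest *n* with *n·d* ≤ zone length, and the vacant
  holes over zone b the smallest *n* with *e_n* ≥ *b*. For reference
  anatomy and the catalogue-mean plate this gives the **3/3/4 rule**:
  3 screws in a, 3 vacant holes over b, 4 screws in c. A brim fracture line
  inside zone b can anchor the vacant run instead (reference hole plus
  third-dependent neighbours).

Because the CT cohorts behind such measurements are not public, the package
includes a parametric generator that builds hemi-pelves *backwards* from
target zone lengths, with exact ground truth, so the whole pipeline is
testable end to end.

## Worked example

Generate a model with reference mean anatomy, measure it, and plan a
10-hole plate:

```
$ brimplan generate --out-dir models --seed 1 --n 1
$ brimplan measure models/pelvis_000_ML.pelvis.json --out zones.csv
$ head -2 zones.csv
file,status,side,sex,a_mm,b_mm,c_mm,total_mm,s_A_from_si_mm,s_B_from_si_mm,circle_radius_mm,circle_max_residual_mm
pelvis_000_ML.pelvis.json,ok,left,male,40.939462,40.650186,57.029755,138.619403,40.939462,81.589648,44.000000,0.000000
```

The generator was asked for zones (40.94, 40.65, 57.03) mm; the landmark
pipeline recovers them to ~5e-4 mm (the brim circle radius 44 mm is
recovered with zero residual on noise-free data). Planning directly from
zone lengths:

```
$ brimplan plan --zones 40.94,40.65,57.03 --out plan.json
3/3/4
```

i.e. 3 screws in zone a, 3 vacant holes over zone b, 4 screws in zone c.
`plan.json` carries the full per-hole schedule plus the safe drilling bands
from the symphysis — here [0, 57.03] mm and [97.68, 138.62] mm, with
(57.03, 97.68) mm off limits. With a fracture line 75 mm from the symphysis
(middle third of zone b) the vacant run re-anchors on the reference hole:

```
$ brimplan plan --zones 40.94,40.65,57.03 --fracture-mm 75
3/3/4
```

The same operations are available as a library:

```python
import brimplan as bp

model, truth = bp.build_pelvis(bp.PelvisSpec(40.94, 40.65, 57.03), seed=1)
lm = bp.compute_landmarks(model)
zones = bp.zone_lengths(model, lm)
plan = bp.plan_plate(lm, zones, bp.mean_plate(), 15.0, 10)
print(plan.summary)            # 3/3/4
```

`brimplan cohort` generates the four reference groups (ML/MR/FL/FR,
n = 28/17/20/15) and reports group summaries with the across-group ANOVA.

See `docs/methods.md` for the model, its assumptions, the synthetic
generator's design and known limitations.

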