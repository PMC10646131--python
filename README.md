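# kneekin

Geometric analysis of tibiofemoral kinematics for weight-bearing knee
studies: from bone/implant surface meshes and rigid-body pose sequences
(the output of 3D-model-to-2D-fluoroscopy registration) to femoral
condylar anterior–posterior (A-P) positions by the **lowest-point
method**, tibial internal–external (I-E) rotation profiles, arcs of
extension, and two-cohort statistics — plus a synthetic knee/TKA
generator with analytic ground truth so the whole chain is testable
without patient data.

Intended users: biomechanics and orthopaedics researchers comparing
native-knee kinematics to total knee arthroplasty (TKA) designs (e.g.
medially conforming, PCL-retaining inserts implanted with kinematic
alignment) during activities such as step up and chair rise.

## Model

For each analysed flexion angle `f` of an activity schedule (step up:
60/45/30/15/0°; chair rise: 90/60/30/0°), the A-P position of each
femoral condyle is the A-P coordinate of the condylar surface point
lowest with respect to the tibial reference plane — the simulated tibial
resection plane for native knees (medial articular plane offset 10 mm
distally, varus–valgus balanced in 2° steps to ±0.5 mm condylar-thickness
agreement), or the baseplate plane for TKA knees, with the tibial origin
at the bounding-box center of the respective contour. Tibial rotation is
the orientation change of the medial–lateral line through the two
condylar lowest points,

```
θ(f) = atan2(AP_med − AP_lat, ML_lat − ML_med),   rotation(f) = θ(f) − θ(0°)
```

positive internal (lateral condyle posterior), from *non-standardized*
positions; A-P positions themselves are standardized to a 50 mm reference
plateau depth for cross-subject comparison. Native tracks average three
registration repeats; TKA tracks are single-pass. Group comparisons are
Welch t-tests at maximum flexion and per arc of extension; the power
analysis (noncentral-t, Welch df, one-sided) gives the minimum detectable
rotation difference for the n = 25 + 25 design. See `docs/methods.md` for
the full construction and its assumptions.

## Worked example

```python
from kneekin import synthetic as syn
from kneekin.pipeline import analyze_knee

model = syn.generate_knee_model()                       # native knee, ~1 mm mesh
motion = syn.MotionSpec(activity="step_up", rotation_path="screw_home")
seq, truth = syn.generate_trajectory(model, motion)     # poses + ground truth
res = analyze_knee(model, seq, "step_up")               # full pipeline
for f, r in zip(res.profile.flexion_deg, res.profile.rotation_deg):
    print(f"{f:5.0f}  {r:6.2f}")
print("max-flexion rotation:", round(res.profile.max_flexion_rotation, 2))
```

prints

```
   60   13.13
   45   12.86
   30   12.18
   15    8.88
    0    0.00
max-flexion rotation: 13.13
```

— the recovered screw-home profile: 13° of internal tibial rotation at
60° flexion (the generator's imposed maximum, recovered within 0.15°),
with 8.9° of it concentrated in the final 15° arc of extension. The four
arc deltas (`res.profile.arcs`) telescope to the maximum-flexion value.

Cohort-level, the same machinery reproduces the structural contrast the
pipeline is built to detect: a 25-knee native cohort (screw-home path)
vs a 25-knee medial-pivot TKA cohort (progressive path) with matched
~13° endpoint rotation shows no difference at maximum flexion
(p ≈ 0.49) but strongly different per-arc rotation (p < 0.001 in the
terminal arc), under default registration noise and 3-repeat averaging.

The same pipeline is scriptable from the shell:

```sh
kneekin simulate --kind native --activity step_up --out demo/
kneekin analyze --model-dir demo/ --poses demo/poses.csv --activity step_up --out demo_results/
kneekin power --n 25 --sd-a 2.9 --sd-b 4.6 --alpha 0.05 --target-power 0.80 --sided one
```

## Layout

```
src/kneekin/synthetic.py   parametric knees, TKA components, motion paths,
                           registration noise, cohorts (+ ground truth)
src/kneekin/frames.py      anatomic axes, flexion angle, sagittal frame,
                           simulated resection plane, tibial frame
src/kneekin/kinematics.py  lowest-point tracking, repeat averaging,
                           standardization, rotation profiles and arcs
src/kneekin/stats.py       Welch/pooled t, chi-square, noncentral-t power
src/kneekin/io.py          STL/PLY meshes, pose CSVs, model directories
src/kneekin/pipeline.py    per-knee and cohort orchestration
src/kneekin/cli.py         kneekin simulate | analyze | stats | power
```
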