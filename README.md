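# spineslip

Automatic detection of lumbar spondylolisthesis — the displacement of a
vertebral body relative to the vertebra below it — from lateral spine
radiographs.  The package is aimed at medical-image-analysis researchers
who want a fully testable reference pipeline: every stage, from
segmentation to the final per-junction decision, can be exercised against
a bundled synthetic spine-phantom generator with exact ground truth, so no
clinical data are required to validate the geometry and decision logic.

## What it does

The pipeline has four stages:

1. **Segmentation** — a two-path fully convolutional network (a U-Net-style
   encoder/decoder plus a stride-2 spatial path, fused by feature fusion
   modules) labels each pixel as background, vertebral body, or sacrum.
   The default configuration takes a 512×512×3 input, produces 5 sigmoid
   output channels, and contains exactly 29 convolution layers.
2. **Geometry** — the label mask is split into 8-connected components;
   each vertebral region is reduced to a quadrilateral by the diagonal
   extreme-point rule (upper-left minimizes x+y, lower-right maximizes
   x+y, upper-right maximizes x−y, lower-left minimizes x−y), ordered
   L1..L5 top-down, with the sacrum contributing its two top-plate points.
3. **Detection** — three rule-based detectors on the fitted corners:
   - **P-grade**: project the lower-right corner p<sub>i,3</sub> of the
     upper vertebra onto the line through the lower top plate
     (p<sub>j,1</sub>, p<sub>j,2</sub>); with slip distance
     A = ‖P<sub>proj</sub> − p<sub>j,2</sub>‖ and plate width
     B = ‖p<sub>j,1</sub> − p<sub>j,2</sub>‖, the P-grade is
     100·A/B, flagged when it exceeds K1 (default 10).
   - **PSD** (piecewise slope detection): along each side of the spine the
     11-point corner chain defines 10 segments; each segment's angle
     against the vertical is θ = cos⁻¹(U·V / ‖U‖‖V‖), and a junction flags
     when a consecutive-angle difference in its segment window exceeds K2
     degrees (default 37; 50 when combined with P-grade).
   - **DS** (dynamic shift): across a flexion/extension pair, the
     plate-normalized slip displacement is measured in each view; a
     junction flags when the absolute difference exceeds K3 (default 0.14).
4. **Grading and metrics** — flagged junctions receive a Meyerding grade
   (1–5, quartering 0–100% with >100% = spondyloptosis); thresholds can be
   re-calibrated by accuracy-maximizing grid search, and evaluation
   produces accuracy / sensitivity / specificity / FP-rate / FN-rate with
   Wilson 95% confidence intervals plus per-region IOU summaries.

## Worked example

```python
from spineslip import (PhantomSpec, Thresholds, detect_case,
                       generate_phantom, geometry_from_mask)

case = generate_phantom(PhantomSpec(slip_junction="L4L5",
                                    slip_fraction=0.3, seed=7))
geometry = geometry_from_mask(case.mask)
report = detect_case(geometry, Thresholds())

for junction, results in report.pgrade.items():
    r = results[0]
    print(f"{junction}: P-grade {r.pgrade:5.1f}%  flag={r.flag}")
print("case positive:", report.case_positive)
print("grades:", {j: g for j, g in report.grades.items()})
```

prints

```
L1L2: P-grade   0.0%  flag=False
L2L3: P-grade   0.0%  flag=False
L3L4: P-grade   0.0%  flag=False
L4L5: P-grade  30.0%  flag=True
case positive: True
grades: {'L4L5': (2, 'low grade')}
```

The phantom was built with a horizontal slip of 0.3 × plate width at
L4–L5, so the measured P-grade of 30% recovers the construction exactly;
30% falls in the 26–50% band, Meyerding grade 2, still "low grade" (the
mild/severe cut sits at 50%).

The same pipeline is available from the shell:

```sh
spineslip phantom --slip 0.3 --junction L4L5 --seed 7 --out demo
spineslip detect --mask demo/phantom_mask.png --out report
```

Other subcommands: `train` (fit the segmentation network on phantoms),
`segment` (apply a checkpoint), `calibrate` (threshold grid search),
`evaluate` (metric table from a predictions CSV).

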