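# Methods

This note records the models, conventions, parameter choices and known
limitations behind `spineslip`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

All geometry uses 0-based pixel coordinates with x rightward (columns) and
y downward (rows); "upper" always means smaller y.  Label masks come in
two dialects: the 7-label dialect (0 background, 1–5 = L1–L5, 6 = sacrum)
produced by the phantom generator, and the collapsed 3-class dialect
(0 background, 1 vertebra, 2 sacrum) used by the segmentation network by
default.  The collapse loses per-vertebra identity on purpose — identity
is recovered downstream by connected components ordered top-down — because
a three-way pixel classification is a much easier learning problem than a
seven-way one and the detectors only need corner geometry, not labels.

## Segmentation network

The network is a two-path fully convolutional design: a four-level
encoder/decoder with skip connections (the downsampling path) plus a
shallow spatial path of stride-2 convolutions, each followed by batch
normalization and ReLU, that preserves high-resolution detail.  Feature
fusion modules (FFM) join the two paths at matching resolutions:
concatenate → 1×1 projection → batch-norm/ReLU → global average pool →
sigmoid channel weights → multiply → add.  One dropout layer sits between
the two bridge convolutions; the final layer is a 1×1 convolution with
per-channel sigmoid output, decoded by argmax.

The default configuration (512×512×3 input, 5 output channels) contains
exactly 29 convolution layers, apportioned as 8 encoder + 2 bridge + 8
decoder + 4 decoder up-projections + 3 spatial path + 3 FFM projections +
1 final.  This apportionment is one consistent realization of the design;
the count is asserted programmatically and a declared
`expected_conv_layers` that the allocation cannot meet raises a
configuration error.  Two open choices were resolved as follows: the
output nonlinearity is a per-channel sigmoid (multi-label form) with
argmax decoding rather than an explicit softmax head, and the loss is the
weighted pixel-wise cross entropy E = −Σ w(x) log p(x) with p the softmax
probability of the true class.  The per-pixel weight map w(x) defaults to
uniform 1.  Training uses Adam (default learning rate 1e-4, 200 epochs for
a full run; the fast configurations used in the tests are noted below).

The numerical layer (convolution via im2col, batch normalization, 2×2 max
pooling, nearest upsampling, dropout with inverted scaling, Adam) is a
small reverse-mode autodiff engine on numpy arrays written for this
package; every operator's backward pass is verified against central finite
differences in the test suite.  Training is deterministic given the seed:
one generator drives initialization, one drives shuffling and dropout.

## Geometry extraction

Foreground regions are 8-connected components per class value; components
below 0.05% of the image area are treated as speckle and dropped
(configurable), and when more than six components survive the six largest
are kept.  Corner fitting uses the diagonal extreme-point rule on the
region's pixels: upper-left = argmin(x+y), lower-right = argmax(x+y),
upper-right = argmax(x−y), lower-left = argmin(x−y).  This reproduces
exact corners for axis-aligned rectangles and stays within rasterization
error for moderate rotations; regions whose extreme points collapse or
whose fitted quadrilateral is a sliver raise a degenerate-region error.
Components are ordered by centroid y.  The sacrum is the lowest component
of the sacrum class when class identity is available, otherwise the lowest
region overall (logged, since the collapse makes this a heuristic); the up
to five regions above it map to L1..L5 top-down.  Missing levels produce a
partial geometry with a warning — detectors then evaluate only junctions
whose both members exist — and nothing is ever fabricated.

## Detectors

All threshold comparisons are strict (">").

**P-grade.**  The lower-right corner of the upper vertebra is projected
orthogonally onto the infinite line through the lower top plate; the
projection may land beyond the plate segment and is measured the same way.
The displacement is computed as the absolute signed position of the
projection along the plate direction measured from the right plate end,
which is algebraically the projection-to-end distance but avoids
floating-point residue at decision boundaries.  Distances are unsigned, so
forward and backward slips both flag; the sign of the position is reported
separately as a direction indicator.  P-grade is invariant to translation,
rotation and uniform scaling of all points.

**PSD.**  Each side's chain is [p1, p4 of L1..L5, then the sacral plate
end]: 11 points, 10 segments, angles in [0°, 180°] against the vertical
V = (0, 1) via the cosine formula.  Junction m (1..4) owns segments
{2m−1, 2m, 2m+1}; the consecutive-difference pairs that stay inside the
window are diffs {2m−1, 2m}; the lumbosacral junction owns segments
{9, 10}, hence diff {9}.  A junction flags when any window diff on either
side exceeds K2.  Because the cosine angle is unsigned, angle differences
are rotation-invariant only while no segment crosses the vertical axis;
this is the operating regime of near-vertical spines and is documented
rather than patched.

**DS.**  The P-grade displacement is measured in each of the two views and
divided by that view's lower-plate length before differencing.  The
threshold K3 = 0.14 is dimensionally a fraction, and normalizing by the
plate (the same denominator as the P-grade) makes the statistic invariant
to the scale difference between two radiographs; the raw-pixel alternative
would not be.  This normalization is a design decision of this package.

**Combination.**  A junction's flag is the logical OR of the available
detectors (P-grade and PSD per view; DS on the pair), which maximizes
sensitivity; a case is positive when any junction flags.  Flagged
junctions carry the Meyerding grade of their maximal view-wise P-grade:
grade 1 for (0, 25], 2 for (25, 50], 3 for (50, 75], 4 for (75, 100],
5 above 100%, with right-closed edges resolving the integer-range
convention for continuous inputs; a P-grade of exactly 0 is grade 1.
Grades 1–2 are "low grade", 3–4 "high grade", 5 "spondyloptosis".

Default thresholds are K1 = 10 (percent), K2 = 37 (degrees) standalone or
50 in combined P-grade+PSD mode (both exposed), K3 = 0.14 (fraction).
A left–right asymmetry variant of the P-grade (>20% abnormal) exists in
the clinical literature but is not connected to any of the K thresholds
and is not implemented.

## Calibration and metrics

Thresholds are "golden values": an exhaustive grid search over candidate
K maximizing accuracy of the decision score > K, ties broken toward the
smallest K (favoring sensitivity), with the full accuracy-vs-K curve
returned for inspection.  Calibration requires at least one positive and
one negative point.

Metrics: accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), FP-rate = FP/N, FN-rate = FN/N (all ×100).  Dividing the
FP/FN rates by total N rather than by condition counts is deliberate: it
is the only definition under which accuracy + FP-rate + FN-rate = 100
holds exactly, an identity the suite property-tests.  Confidence intervals
are Wilson score by default (well-behaved near 0% and 100%), with a
normal-approximation option.  Ratios with zero denominators are reported
as not-available, never silently 0.  Segmentation is scored by per-region
IOU with the mean over regions present in either mask, a region counting
as detected when its IOU exceeds 0.5.

## The phantom generator

The generator emulates the geometry of a lateral lumbar radiograph: six
stacked bone regions (five rectangular vertebral bodies and a trapezoidal
sacrum whose top plate spans the full width), rendered as filled
quadrilaterals with a one-pixel brighter cortical rim on a darker
background with additive Gaussian noise (default sd 6 gray levels), an
optional rigid global tilt, and a purely horizontal translation of the
stack above a chosen junction by slip_fraction × plate_width.  By
construction the P-grade at the slipped junction equals 100 × slip_fraction
and all other junctions are 0.  Default canvas 320×256 with a 100-pixel
plate; plates are corner-inclusive (a plate from x0 to x0+w covers w+1
pixel columns) so the fitted plate length equals w exactly and measured
slips agree with the construction whenever slip × width is an integer —
this keeps decision-boundary cases exact on rasters.  A junction's truth
label is positive when its constructed P-grade exceeds 10 (the default
K1).  Cohorts draw positive slips uniformly from [0.15, 0.5] and negative
slips from [0, 0.05] so that a separating threshold exists and calibration
recovery is well-posed.  Flexion/extension pairs share all anatomy and
differ only in slip (and noise seed); the shared-anatomy assumption is a
construction of this package, not a property of real paired radiographs.

What the phantom does **not** emulate: osteoporotic texture, osteophytes,
pelvic superimposition, sacralization variants, perspective or exposure
effects, or anatomical shape variation.  Passing tests therefore
demonstrate that the measurement and decision chain is correct on
geometrically faithful input; they say nothing about segmentation
robustness on clinical images.

## Problem sizes used in the tests

The suite favors small, deterministic configurations: gradient checks run
on tensors of a few hundred elements; the smoke-training check uses 20
training and 4 held-out 64×64 phantoms, base_filters = 4, 40 epochs at
learning rate 3e-3 (the loss-trend assertion compares successive
10-epoch means), asserting held-out foreground IOU > 0.6; the oracle
equivalence check uses 1000 random quad/plate pairs against a
dense-sampling projection oracle with parabolic vertex refinement; the
recovery sweep covers slips 0–0.5 in steps of 0.05 over 3 seeds; the
calibration recovery uses a 40-case (200-junction) cohort.

## Known limitations

- Vertebra identity is positional (top-down), not anatomical; under
  sacralization or a missed level the naming can shift by one.
- The PSD angle is unsigned, so its rotation invariance breaks when
  segments straddle the vertical; extreme tilts can mask or exaggerate a
  slope difference.
- The DS normalization assumes both views expose the same lower plate; a
  badly fitted plate in one view biases the shift.
- The extreme-point corner rule degrades beyond ~45° of rotation and on
  regions with protruding artifacts (the osteophyte failure mode).
- The autodiff engine is written for clarity and testability, not speed;
  full-resolution (512×512) training is possible but slow, and realistic
  use at that scale would batch on a faster backend.
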