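# Methods

## Problem and representation

`pigparts` detects the position and orientation of every pig visible in a
top-down image of a group-housing pen. Each animal is summarized by four
back-surface keypoints — left ear *l*, right ear *r*, shoulder *s* (center
ridge between the shoulder blades) and tail *t* (center ridge between the
hams) — and an instance is defined as a joined shoulder–tail pair.
Detection is bottom-up: all parts are found first, in image space, and
grouped into animals afterwards, which avoids the bounding-box overlap
failure of region-proposal detectors when animals lie pressed together.

The target representation has 16 image-space channels at input resolution:

* **Channels 1–4 (part heatmaps).** Each annotated part contributes an
  isotropic Gaussian kernel, scaled to peak value 1.0 so a single fixed
  threshold works across animal sizes. Overlapping same-channel kernels
  combine by pointwise maximum (which preserves each peak exactly).
  The per-instance kernel width is

      sigma_n = 0.16 * (mu_st + delta_st_n)

  where `delta_st_n` is instance *n*'s shoulder–tail length and `mu_st`
  the frame mean; mixing the two keeps kernels from collapsing on
  foreshortened bodies.

* **Channels 5–16 (association fields).** Six directed part pairs
  (l→s, s→l, r→s, s→r, s→t, t→s) each occupy an (x, y) channel pair. In
  a disc around the *source* part the constant pixel offset
  `source − partner` is stored. The disc is the region where the source
  kernel exceeds magnitude 0.2, i.e. radius `sigma_n * sqrt(−2 ln 0.2)
  ≈ 1.794 sigma_n`. Where discs of different instances intersect on one
  channel the stored vector is the kernel-magnitude-weighted mean of the
  contributors (generalized to any number of contributors). An explicit
  binary assignment mask is stored alongside, so a genuine zero offset
  component is never confused with "unassigned".

Coordinates are 0-based with x indexing columns, y indexing rows, and
pixel centers at integer coordinates. Kernels are truncated at 4 sigma
when rendered (dropped values < 3.4e−4, below every decoder threshold).

## Decoding

1. All 16 channels are smoothed with a 5×5 averaging box filter
   (replicate borders) — a no-op in spirit for exact targets, noise
   suppression for network outputs.
2. Part peaks are pixels that attain the maximum of their centered
   15×15 window and exceed the detection threshold (default 0.25).
   Plateaus of tied maxima collapse to their lexicographically smallest
   (y, x) pixel. Peaks are refined per axis by the three-point parabola
   vertex `delta = (v− − v+)/(2(v− − 2 v0 + v+))`; refinement is skipped
   at borders, for non-negative curvature, or when |delta| > 0.5, where
   the vertex is meaningless.
3. For each directed pair, sampling the association channels at a
   detected source (bilinear, at the refined sub-pixel position) and
   subtracting gives the estimated partner location. The association
   distance between detections `p_n, q_m` is the mean of the forward and
   backward prediction errors. This yields three distance matrices
   (l,s), (r,s), (s,t).
4. Each matrix is solved by the Hungarian algorithm
   (`scipy.optimize.linear_sum_assignment`), deliberately without a
   maximum-distance gate (no resolution-dependent parameters). Matched
   shoulder–tail pairs become instances; ear assignments attach only to
   shoulders that formed an instance. Instance confidence — plumbing the
   published method does not define — is the minimum peak value among
   the constituent parts.

A Euclidean baseline replaces the association distance with the plain
point distance; it exists for the ablation comparison and fails in the
documented close-proximity regimes (opposed-heading side-by-side pairs,
closed head-to-tail rings) where the nearest tail belongs to a
neighbour.

## Evaluation

Only shoulders and tails define instance identity. A ground truth *n*
and a detection *m* match iff each is the other's argmin of
`|s_n − s̃_m| + |t_n − t̃_m|` (mutual nearest neighbour, "cross-check").
Unlike an unparameterized Hungarian assignment this never force-matches
far-away pairs, and it needs no distance threshold. Argmin ties break
toward the lowest index, which resolves mutuality-ambiguous ties as
no-match. Precision/recall/F aggregate micro-style (counts summed over
the frame set before dividing). Empty-set conventions: precision is 1
with no detections, recall 1 with no ground truth, F 0 when P + R = 0.

## Network

A 41-block hourglass: input; five encoder levels of 3×3 conv blocks
(conv + batch norm + ReLU; 2, 2, 3, 3, 3 blocks per level) each closed
by 2×2 max pooling; five max-unpooling stages that reuse the pooling
indices of their mirrored pooling layer; depth concatenation of the
symmetric encoder feature immediately after the first four unpoolings;
and a final 3×3 convolution to 16 channels. With conv width 3, pooling
stride 2, unpooling stride 0.5 and pooling kernel width lower-bounded at
1, the effective-stride and receptive-field recursions give a bottleneck
stride of 32 and an output receptive field of 363 px (radius 181),
larger than the longest bodies (~140 px) at the 480-column working
scale. A concat after the fifth unpool is omitted by design: the block
and receptive-field budget admits no clean conv profile with one, and at
full resolution the skip would only re-inject the two earliest feature
maps; the fifth unpool feeds the output convolution directly.

Channel widths per level default to (16, 32, 64, 128, 320), chosen to
land near a 4.0M-coefficient budget (the only printed constraint);
`SMALL_WIDTHS = (8, 16, 24, 32, 48)` is the desk-scale profile. The
implementation is a NumPy layer stack with hand-written backprop
(im2col convolution, spatial batch norm, pooling with stored indices);
training runs one image per step with Adam.

**Selective loss.** Mean-squared error over all pixels of the part
channels plus mean-squared error over mask-assigned pixels only of the
association channels, each term normalized by its own pixel count.
Gradients at unassigned association pixels are exactly zero, separating
the detection and association tasks. The public `selective_loss`
reports this unweighted two-term sum.

The trainer applies three positive reweightings that change only the
optimization dynamics, never the optimum (targets are deterministic
given the image, and every per-pixel weight is positive, so the
pointwise minimizer remains `prediction = target`):

* `assoc_weight` (default 1e−3) rescales the association term, whose
  raw magnitude (offsets are tens of pixels) is 3–4 orders above the
  unit-peak heatmap term and would otherwise consume nearly all of the
  shared-feature gradient;
* part-channel pixels are weighted `1 + 4·target + 10·|error|`: the
  `target` term counters the empty-background dominance that makes
  plain MSE raise peak amplitudes very slowly, and the `|error|` term
  accelerates suppression of spurious mid-amplitude responses (ghost
  peaks at the wrong body end while orientation is still being
  learned). At desk-scale step counts these reweightings are the
  difference between a threshold-separable output and one where true
  peaks and ghosts share the 0.2–0.4 amplitude band.

**Normalization.** Training runs one image per step, so the conv-block
normalization is per-image over space (instance-norm semantics).
Inference uses the same per-image statistics: running averages are not
a stable surrogate here, since at the bottleneck they would be
estimated from a spatial sample of a few dozen pixels, and a
train/inference statistics mismatch grows with the learned scale
parameters.

## Augmentation

Draws combine a left-right flip (p = 0.5), rotation uniform in
[0°, 360°), isotropic scale uniform in [0.5, 1.5] and XY shifts uniform
in ±20 px. The training path transforms the *annotations* and
re-encodes, keeping kernels sharp; map-space warping (bilinear for
heatmaps, nearest for association values and mask) exists for parity
checks and must commute with re-encoding to within 0.5 px
(`consistency_check`). A flip swaps the ear labels, hence part channels
l↔r and the (l↔s)/(r↔s) channel groups, and every stored offset is
transformed by the draw's full 2×2 linear map (flip reflection included,
rotation matrix R = [[cos, −sin], [sin, cos]] — positive angles rotate
+x toward +y). Instances whose shoulder or tail leaves the frame are
dropped; ears are dropped individually.

## Synthetic scenes

The generator emulates the *geometry* of overhead pen footage, not its
appearance: elongated elliptical bodies (full width 0.42 L) with a head
disc and ear nubs on a textured floor, optional pen-mask polygon with
outside pixels blacked, additive Gaussian noise. The head end is
rendered clearly darker than the body: it is the one appearance feature
the task cannot do without, since a front-back visually symmetric body
leaves the shoulder/tail orientation unlearnable, which no real
overhead footage suffers from. Keypoint placement is a
fixture convention: tail at the rear major-axis end, shoulder 70% along
the major axis, ears flanking the 95% point at ±0.25 L laterally; the
animal's left is (u_y, −u_x) for heading u in image coordinates. Body
lengths draw from a triangular distribution (mode at 36% of the range)
so most bodies are short with a tail of long ones; the default range is
30–140 px at the 480-column scale. A configurable fraction of animals
is placed as abutting side-by-side pairs (shared orientation, lateral
gap drawn from [−0.3, 0) widths — slight overlap, as when animals press
together — and ±0.25 L longitudinal stagger).

What passing tests on these scenes do show: the encoder, decoder,
grouping, matching and training loop are internally consistent and the
network can learn the representation from images. What they do not
show: robustness to real texture, lighting, occlusion or unseen
environments — the synthetic appearance model is deliberately trivial.

Deterministic suites:

* `round_trip_frames` — pigs on a jittered 4×3 grid of a 384×512 canvas
  (lengths 30–60 px) so every cross-instance part separation exceeds
  2·max sigma by construction (asserted per frame); the conditions under
  which encode→decode must be an exact round trip (sub-0.5 px).
* `generate_fixture_suite` — six named fixtures: single pig, abutting
  pair (opposed headings), head-to-tail chain, pig at the mask border
  with ears beyond it, dense 12-pig pen, empty pen.
* `abutting_suite` — the close-proximity ablation suite: two
  opposed-heading pairs plus closed head-to-tail rings of three and
  four. Opposed-heading pairs make Euclidean grouping swap partners
  (every 2-swap detection still cross-check-matches, since it shares its
  endpoints with two truths); the rings make the swapped stubs fail
  mutuality and produce genuine false positives, which is what separates
  the two modes' precision. Ring gaps are deliberately unequal to break
  argmin ties. Geometry was verified numerically before freezing.

## Desk-scale training suite

250 scenes at 160×224 px (2–4 pigs, bodies 32–60 px, abutting fraction
0.25) split 200 train / 50 held-out; the small width profile; 14 epochs
of single-image Adam steps (lr 1e−2 halving over the run); augmentation
with full flips and rotations but scale (0.75, 1.3) and shifts ±10 px,
proportionate to the half-resolution scenes. The held-out bar (recall
and precision > 0.9 at threshold 0.25) is a property-based stand-in for
corpus-scale results: it demonstrates the pipeline is trainable
end-to-end, not that any real-world accuracy is reproduced. Under these
conditions the ground-truth encodings decode perfectly, so the ceiling
is not data-limited.

## Numerical choices and degenerate inputs

* Annotations with coincident shoulder and tail are readable but
  rejected by the encoder (no orientation, no kernel size).
* An empty frame encodes to all-zero maps and decodes to an empty set;
  metrics on empty/empty are all 1.
* Peak-plateau ties: lexicographically smallest (y, x) wins.
* Hungarian input may be rectangular; |Np − Nq| parts stay unmatched.
* Sub-pixel refinement guards: border peaks, non-negative curvature and
  |delta| > 0.5 all leave the axis unrefined.
* Network inputs not divisible by 32 are reflect-padded and the output
  cropped (`predict_maps`); `forward` itself insists on multiples of 32.
* Training aborts with the loss history attached if the loss goes
  non-finite.

## Known limitations

* One part instance per image location: coinciding same-type parts of
  different animals cannot both be represented or detected.
* Ears are attached but not evaluated; instance identity rests on
  shoulder and tail alone.
* The synthetic appearance model cannot probe lighting or texture
  robustness, and no photometric augmentation is implemented.
* The NumPy network trains single-image batches only; normalization is
  per image over space at both training and inference.
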