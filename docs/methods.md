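# Methods

## Scope and model of the data

`streetads` treats an advertisement survey as a sequence of geo-tagged
frames sampled at a fixed time interval (default 0.5 s) along a route,
each paired with a per-pixel semantic label map in which advertisement
pixels carry one of four content categories (food, alcohol, gambling,
other; 0 = background). The package deliberately does not contain the
segmentation network that produces such maps for real photographs: a
`SegmentationBackend` contract (oracle replaying fixture ground truth, or
a PNG adapter reading externally produced maps) is the seam. The same
pattern covers the learned rectifier (`RectifierContract`) and the deep
classifier (`ClassifierContract`): the pipeline's logic, parameters and
evaluation protocol are fully implemented and tested; heavy learned
components are plug-ins.

## Extraction

Billboard pixels are grouped into connected components (8-connectivity,
matching the common default of connected-components-with-stats routines;
4-connectivity is available). Each component gets a convex hull, computed
on pixel centres and filled by `skimage.morphology.convex_hull_image`; the
filled area is the instance's size. Components whose *filled hull* covers
fewer than 2 000 px are discarded — small adverts cannot be reliably
categorised. The boundary is kept: exactly 2 000 px passes. The filter is
applied to the filled hull rather than the raw component because the
object being filtered is the polygon; for convex planted fixtures the two
coincide, and the choice is isolated behind the `min_area` parameter for
sensitivity analysis.

An instance's geotag is its source frame's capture point. This is an
approximation (the billboard itself stands some metres away); it is the
only position available without depth estimation, and the deduplication
distance parameter absorbs it.

## Rectification

The default rectifier is purely geometric. A minimum-area enclosing
quadrilateral is fitted to the hull with the classic edge-collapse
heuristic: while more than four vertices remain, the edge whose removal
(replacing it by the intersection of its neighbours' support lines) adds
the least area is collapsed. The result always encloses the hull;
triangles are promoted by splitting their longest edge. The quad is then
mapped by homography onto a fixed 224 × 224 upright rectangle with
bilinear interpolation, zero fill outside the source (consistent with
hull masking). On fixtures built by applying a known homography to a
square texture the fitted corners land within 2 px of the true corners
and the round trip reconstructs the texture to a mean absolute error of a
few intensity units away from the border.

## Duplicate suppression

Sampling frames every 0.5 s records the same physical billboard several
times. Suppression proceeds exactly as: candidate pairs are instances
whose capture points lie within *d* metres (inclusive; computed with
haversine — at *d* = 10 m geodesic and planar Euclidean distances are
indistinguishable); a feature matcher counts keypoint matches between the
two crops; an edge is added when the count strictly exceeds τ; each
connected component of the resulting graph is one physical advert and
only the member nearest (geodesically) the arithmetic mean of member
coordinates is retained, ties broken by smallest instance id after
rounding distances to a micrometre so exact geometric ties are
deterministic. Defaults are τ = 60, *d* = 10 m.

The default matcher is SIFT (scikit-image) with cross-checked
nearest-neighbour matching under Lowe's ratio test at 0.75. The ratio
test is direction-dependent, so the pair is canonically ordered by a
content digest before matching, making the count symmetric as the
contract requires. An `ExactTextureMatcher` — downscaled-crop Pearson
correlation thresholded at 0.8, returning a fixed large count — serves as
the deterministic oracle in tests; it identifies *textures*, so two
same-category billboards with strongly similar procedural patterns can
correlate highly, which is why test fixtures separate distinct billboards
by more than *d*.

Deduplication is idempotent for a deterministic matcher, order-invariant
under the tie-break above, and monotone: the retained count is
non-decreasing in τ (fewer edges ⇒ finer partition) and non-increasing in
*d*.

## Classification

`TrainConfig` carries the training schedule: five 100-step epochs, batch
32, learning rate 1e-4, 224-px inputs, ±30° rotation augmentation. The
desk-scale default classifier honours the schedule by drawing
`epochs × steps_per_epoch` batches of rotation-augmented samples from the
oversampled training set, featurising them (per-channel 8-bin intensity
histograms, channel moments, gradient-magnitude statistics on a 48 × 48
downscale) and fitting a multinomial logistic regression on the pooled
draws; the learning rate is meaningful only to gradient-trained plug-ins
and is documented as such. Oversampling raises every class to the
majority count by resampling with replacement, never dropping a sample.

Evaluation uses support-weighted precision/recall/F1 (per-class metrics
from the confusion matrix, aggregated by class share of true labels;
zero-denominator classes contribute 0 with a warning) and the balanced
subset protocol: the dominant class is sampled down, without replacement
within each of k = 5 subsets, to the minority class's size, and per-class
metrics are averaged across subsets.

## Exposure analysis

Frames are point-in-polygon joined to zone polygons carrying a
deprivation decile (1 = most deprived, following the English Indices of
Deprivation convention) and an output-area-classification supergroup
(1–8) / group (26 codes). Boundary points go to the lowest zone id whose
closed polygon covers them; frames outside every zone are counted as
unassigned and excluded from groups. The exposure percentage of a
category in a group is 100 × (frames containing ≥ 1 representative advert
of the category) / (frames in the group), rounded to two decimals for
reporting. Only deduplication representatives are counted by the pipeline
(pre-dedup counts are available by passing the raw instance list).

Independence of exposure and grouping is tested per category with
Pearson's χ² on the 2 × k table of frames-with vs frames-without across
groups — the same unit (images) the exposure percentages use. The
statistic, (r−1)(k−1) degrees of freedom and upper-tail p-value come from
`scipy.stats.chi2_contingency` without continuity correction; expected
counts below 5 raise a warning. Significance stars: * < 0.05, ** < 0.01,
*** < 0.001. No multiple-testing correction is applied across the
category × grouping grid; consumers who need family-wise control should
apply their own.

## Synthetic fixtures

The generator emulates the statistical structure the pipeline assumes:

- **Routes** are straight lines at constant speed (default 10 m/s) and
  heading, sampled at 0.5 s, so consecutive frames are exactly 5 m apart
  and inter-observation distances are analytic. Real survey routes are
  irregular; nothing in the pipeline depends on straightness.
- **Billboards** are planted as quadrilaterals per frame, with a
  per-billboard procedural texture: a category-keyed palette and base
  pattern (checker/stripes) plus seeded coarse blobs and fine speckle
  that make keypoint descriptors distinctive per physical billboard. The
  standard plan re-observes each billboard in 2–4 consecutive frames with
  a small drift and shrink of the quad, mimicking a moving camera, and
  separates distinct billboards by several frame gaps (> 10 m). Default
  billboards are 120 × 95 px in 300 × 400 px frames (≳ 11 000 px, well
  above the 2 000 px filter and enough surface for stable keypoints).
- **Label maps** carry the true category id on exactly the rasterised
  quad pixels (inclusive-corner convention: a w × h rectangle covers
  exactly w·h pixels), so extraction counts are pixel-exact.
- **Zones** tile a bounding box with a grid; deciles and OAC groups are
  drawn deterministically from the attribute seed.

Equal seeds give bit-identical bundles (all randomness flows through
explicitly seeded generators; no process-dependent hashing).

What passing on these fixtures does **not** show: robustness to real
photographs — occlusion, motion blur, lighting, non-planar or bezel-less
signage, segmentation errors, and visually similar adverts of different
brands are all absent by construction. The fixtures verify the pipeline's
logic, thresholds and bookkeeping, not the perception quality of any
learned backend.

## Numerical choices and degenerate inputs

- Area filter boundary inclusive (≥ 2 000 px); τ strict (> 60); distance
  inclusive (≤ d).
- mIoU is pixel-pooled over the considered images (micro) because a
  single per-category value is reported; per-image macro averaging is an
  option. An empty considered set or a category absent from both sides
  raises an explicit `UndefinedResultError`, never a silent 0.
- The detection audit greedily matches extractions to truth footprints by
  descending polygon IoU at threshold 0.5, ties by lower instance id then
  truth id; hull polygons are buffered by half a pixel to reconcile
  pixel-centre hulls with inclusive-corner truth quads.
- Degenerate geometry (collinear hulls) raises
  `DegenerateGeometryError`; 1-pixel warp outputs return the region mean;
  single-pixel components degenerate to unit-area hulls.
- χ² on proportional integer tables returns exactly 0 (expected counts
  are exact integer ratios in floating point).

## Simulation scales

The null-calibration and power checks of the decile test simulate, per
replicate, binomial frames-with-advert counts in 10 deciles of 500 frames
each — a modest survey of 5 000 frames, at which the χ² asymptotics are
accurate (at 200 frames per decile the test over-rejects slightly). Null
uses a common 10 % exposure rate; the power scenario triples the rate in
deciles 1–5 (15 % vs 5 %). 200 seeded replicates give a rejection-rate
standard error of ≈ 0.015 under the null. The end-to-end fixture plants
12 billboards (three per category) over an 88-frame route; with 2–4
observations each this yields 30–45 extracted instances and runs in well
under a minute including classifier training at the default schedule.

## Known limitations

- Instance geotags are capture points, so two different billboards seen
  from the same spot are distinguished only by the feature matcher.
- Residual duplication is possible when the same physical advert is
  observed at points more than *d* apart with no connecting chain.
- The desk classifier is a linear model on global histograms; it is a
  contract default for testing and desk-scale use, not a substitute for a
  deep backbone on real imagery.
- The exposure analysis conditions on frames, not on viewable area or
  dwell time; population-flow-based exposure is out of scope.
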