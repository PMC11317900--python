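# Methods

## Geometry and coordinate conventions

A CT volume is a scalar grid indexed `(x, y, z)` with isotropic voxel size
in µm; all computation is in voxel units and physical units are obtained by
multiplying at reporting time. Coordinates are 0-based with voxel/pixel
centres at integer positions. The bud rotation axis is the vertical grid
line through the continuous grid centre `((Nx−1)/2, (Ny−1)/2)` — symmetric
for odd and even dimensions. Tilted samples are aligned by a rigid map that
sends a user-estimated axis (a point plus a unit direction, determined by
visual inspection; automatic axis detection is out of scope) onto that
vertical line, with the axis point closest to the grid centre mapping
exactly onto the centre. Resampling is nearest-neighbour, both for the
alignment rotation and for slicing, so voxel value statistics are not
smoothed; the interpolation order for the alignment rotation is not
externally constrained, and nearest neighbour was chosen to match the
slicing interpolation. Out-of-grid samples are filled with the mean of all
source voxel values, keeping the intensity statistics of generated images
comparable to real ones.

A slice plane at azimuth θ contains the rotation axis. Horizontal pixel
index `h` maps to a *signed* radius `r = h − (width−1)/2`, so one image
spans the full diameter and θ only needs to cover [0°, 180°): at the
production increment of 0.05° this yields 3600 images, and at the
annotation increments 7.5° and 45° it yields 24 and 4. Image width is
`min(Nx, Ny)` and height is `Nz`. Nearest-neighbour ties round half away
from zero (fixed, documented, and exercised by the impulse tests).

Adjacent planes fan out from the axis, so the worst-case tangential gap at
radius `w` px with increment Δθ is `w / (90°/Δθ)` — for a 2048 px volume at
0.05°, 1800 planes per quadrant and ≈1.14 px (≈3.13 µm at 2.75 µm/voxel).
This bound is both an exported calculator and the error budget used by the
simulator tests: a noiselessly detected point back-projects to within
`max(capture halfwidth, tangential bound)` of the truth.

## Detection metrics

Boxes are continuous half-open regions `[x_min, x_max) × [y_min, y_max)`,
making areas exact and integer-aligned boxes rasterise unambiguously; the
closed-form box IoU is tested against a pixel-set counting oracle.
Matching is greedy in confidence rank order (stable for ties), each ground
truth usable once, pooled across slices but matched within a slice. A
detection is correct only when IoU is *strictly greater* than the
threshold — the wording of the protocol this package follows, where COCO
proper uses ≥; at IoU exactly 0.60 this makes the 0.60 threshold fail, so a
detector with uniform IoU 0.6 scores AP50 = 1, AP75 = 0, AP(0.5:0.95) = 0.2.
AP uses 101-point interpolation (max precision at any recall ≥ r, averaged
over r = 0.00, 0.01, …, 1.00), pinned as the concrete reading of "as in MS
COCO". Dice is `2|P∩G|/(|P|+|G|)`; the identity `Dice = 2·IoU/(1+IoU)` is
asserted on random masks.

## False-positive gating

Wrong contact-point detections concentrate in floret tissue, while contact
points by definition touch the receptacle. A detection is kept iff at least
one mask-true pixel centre lies inside its half-open box; no area threshold
is applied because the decision in the source protocol is binary. The
filter is idempotent and monotone in the mask, both property-tested.

## Integration and clustering

The centre of each kept box is back-projected through the plane
parameterisation (box size is deliberately irrelevant: only positions are
analysed, and the centre is the symmetric choice). Because a contact point
has physical extent it appears on several adjacent planes, each detection
carrying positional error, so the cloud of back-projected points is
condensed by group-average agglomerative clustering: inter-cluster distance
is the mean of all pairwise Euclidean distances, merging proceeds while the
smallest inter-cluster distance is < d and terminates once it is ≥ d
(strict-below merging; the ≥ reading of the termination condition is the
more precise of the two available phrasings and is the one implemented).
Hierarchical clustering needs no prior cluster count — essential because
the floret count is unknown. The implementation updates distances with the
exact average-linkage Lance–Williams recurrence in O(n²) per merge;
correctness is defined by (and tested against) a naive oracle that
recomputes every inter-cluster distance from member lists each iteration,
and independently cross-checked against SciPy's average-linkage tree cut at
d. Equal minima are broken deterministically by the lexicographically
smallest pair of cluster-creation indices (singletons numbered in input
order, merged clusters onward); ties are measure-zero for real data but the
rule makes runs reproducible bit-for-bit.

Cluster centroids are the contact-point estimates; the cluster count is the
floret-count estimate. Averaging N detections with i.i.d. zero-mean jitter
drives the centroid error towards zero as N grows — measured directly: mean
centroid error ≈ 0.55 px with 5 supporting slices vs ≈ 0.13 px with 100, at
1 px jitter (200 replicates). Duplicate detections on one slice are not
deduplicated before integration; clustering absorbs them.

d is a free parameter with no automatic selector (deliberately out of
scope). The package exposes the count-vs-d sweep over {1, 10, 20, 30, 40,
50} as the practical selection tool: counts are non-increasing in d
(property-tested), over-segmentation shows as a steep drop at small d and
over-grouping as a continued decline past the plateau; the plateau is the
operating point. At d → 0⁺ every distinct point is a singleton; beyond the
data diameter there is one cluster.

Evaluation matches each estimate to its *nearest* ground-truth point
(brute-force-verified k-d tree), reporting per-point errors, their mean and
population standard deviation (the convention here; the sample/population
choice was not externally pinned), each estimate's radial distance from the
axis, and nearest-floret distances for spacing analysis.

## Synthetic buds

The generator emulates exactly the geometry the pipeline consumes, not the
physics that produced it. The receptacle is a surface of revolution: a cone
`z = apex − r/tan α` (default half-angle 45°) or paraboloid
`z = apex − r²/c`. Contact points follow a Vogel spiral — point k at
azimuth k·137.508° and radius `c√k` clipped to the rim — chosen as the
phyllotaxis stand-in because it gives the apex-dense, roughly uniform
packing real capitula show; no claim is made that real florets follow it
exactly. Defaults describe a late-stage bud at the study's scale: 90
florets, base radius 400 px, apex height 460 px, spiral scale 25 px. The
spiral scale is a fixed spacing (not derived from the rim radius) so that
nearest-neighbour inter-floret distances come out around 50 px, the spacing
observed on real late-stage buds, and so that a single floret sits near the
apex rather than on the rim.

The noise model has five parameters: `capture_halfwidth_px` (default 3 px)
models the physical extent of a contact point — it is detected on every
plane passing within that perpendicular distance, hence on more planes near
the axis; `jitter_sigma_px` (default 1 px) is in-plane Gaussian detection
error; `p_miss` a per-opportunity miss probability; `fp_rate` the Poisson
mean of per-slice false positives; `box_size_px` (default 8 px) the emitted
box side. False positives are placed uniformly over pixel centres whose
entire box clears the receptacle mask (mask dilated by the box footprint),
so the mask-overlap filter's effect is measurable in isolation: 100%
removal of planted false positives and 100% retention of true detections is
an exact property of the construction, not a statistical outcome. True and
false detections carry confidences drawn from [0.6, 1.0) and [0.05, 0.6)
respectively. With all noise at zero the generator reproduces the idealised
setting in which slice coordinates of every contact point are known, used
to isolate the error contributed by the slicing geometry itself. All
outputs are deterministic given spec and seed.

What the simulator does *not* model: X-ray photometry and reconstruction
artefacts, involucre/floret anatomy, non-symmetric receptacles, growth
stages, confidence–accuracy correlation of real detectors, and spatially
correlated detection error. Tests passing on synthetic buds therefore
validate the geometry, filtering and clustering machinery — not the
performance of any particular neural detector on real tissue, which must be
measured with the metrics module on annotated slices.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery experiment at
0.5° slicing (360 planes, ~300–600 integrated points) on an 850×520 px
plane — the same geometry as the production setting at a slice density that
keeps the whole suite under a minute while leaving the tangential spacing
at the rim (≈3.5 px at r = 400) large enough to be the dominant error term,
which is the regime worth testing. Under those conditions the pipeline
recovers exactly 90 of 90 planted florets with mean position error
≈ 0.27 px (noiseless) and mean nearest-floret-distance error ≈ 0.23 px for
points more than 20 px from the axis. Points close to the axis sit at the
crowded apex where a single global d over-merges; the error-vs-axis scatter
plot (`plotting.plot_error_vs_axis`) is the diagnostic for that regime, and
adaptive per-region thresholds are explicitly out of scope.

Degenerate inputs are rejected rather than guessed at: empty point sets,
non-positive thresholds and voxel sizes, zero-area boxes, two empty masks
in a Dice/IoU call, axis directions antiparallel to z (rotation ill-posed),
angular increments that do not divide 180°, and detections paired with a
mask or plane from a different slice. The clustering threshold comparison,
the IoU threshold comparison and the nearest-neighbour rounding rule are
the three places where strict-vs-inclusive inequalities change results;
each is fixed above and locked by a unit test.

## Known limitations

Single global d (no automatic or adaptive selection); no surface
reconstruction (point clouds are exported as PLY for external meshers); no
neural detector/segmenter (external by design); axis estimation is manual;
rotational symmetry of the specimen is assumed throughout — strongly
asymmetric buds violate the premise of radial reslicing.
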