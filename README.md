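# capitulum3d

Estimation of the 3D positions of floret–receptacle contact points inside
composite flower buds (Asteraceae capitula, e.g. *Chrysanthemum seticuspe*)
from micro-CT volumes.

A capitulum packs many florets onto a roughly cone-shaped receptacle that is
rotationally symmetric about a vertical axis. The points where florets meet
the receptacle encode the phyllotactic arrangement of the inflorescence, but
they sit deep inside the bud and can only be observed non-destructively in a
CT volume. `capitulum3d` implements the full geometry pipeline around an
external 2D detector/segmenter:

1. **Radial reslicing** — the volume is cut along planes *containing* the
   rotation axis at a fixed angular increment (e.g. 0.05°, giving 3600
   images over [0°, 180°) since each mid-longitudinal image spans the full
   diameter). Organs look the same on every such slice, which is what makes
   2D detection tractable. Tilted samples are first axis-aligned from a
   user-supplied axis estimate.
2. **Detection evaluation** — IoU, COCO-style AP (AP50, AP75, AP(0.5:0.95),
   101-point interpolation, strict "greater-than" IoU thresholding) and the
   Dice coefficient, for scoring any external contact-point detector and
   receptacle segmenter whose outputs the pipeline consumes.
3. **False-positive removal** — wrong detections concentrate in floret
   tissue, so any detection whose bounding box contains no receptacle-mask
   pixel is discarded.
4. **3D integration + clustering** — each contact point has physical extent
   and is seen on several adjacent slices with positional error, so kept
   detections are back-projected into voxel coordinates and condensed by
   group-average agglomerative clustering. Inter-cluster distance is

   d(A, B) = (1 / |A||B|) · Σ_{x∈A} Σ_{y∈B} ‖x − y‖,

   and merging stops once the smallest d(A, B) ≥ d, a threshold in voxel
   units. Cluster centroids are the contact-point estimates; averaging
   cancels zero-mean detection jitter, and the number of clusters needs no
   prior knowledge of the floret count.
5. **Synthetic buds** — a generator for conical/paraboloidal receptacles
   with golden-angle (Vogel-spiral) contact points, per-slice masks and a
   detection-noise model (jitter, misses, off-receptacle false positives),
   so every stage runs and is tested without CT data.

## Worked example

Simulate a noisy 90-floret bud, gate detections by the receptacle mask,
integrate, sweep the clustering threshold and evaluate:

```python
import numpy as np
import capitulum3d as c3d

spec = c3d.BudSpec(n_florets=90, base_radius_px=400, apex_z=460, seed=0)
noise = c3d.NoiseSpec(jitter_sigma_px=1.0, p_miss=0.1, fp_rate=0.5)

planes = c3d.generate_planes(0.5, spec.center_xy, width=850, height=520)
gt, _ = c3d.make_bud(spec)
masks = c3d.render_masks(spec, planes)
dets = c3d.simulate_detections(gt, planes, noise, masks, np.random.default_rng(0))

by_mask = {m.slice_id: m for m in masks}
kept = []
for p in planes:
    k, _ = c3d.filter_detections([d for d in dets if d.slice_id == p.slice_id], by_mask[p.slice_id])
    kept += k
print(f"detections: {len(dets)} total, {len(kept)} kept after receptacle gating")

by_plane = {p.slice_id: p for p in planes}
points = np.array([c3d.backproject(d, by_plane[d.slice_id]).xyz for d in kept])

counts = c3d.sweep_cluster_counts(points, [1, 10, 20, 30, 40, 50])
print("clusters vs d:", {int(d): n for d, n in counts.items()})

clusters = c3d.agglomerate(points, d=20.0)
est = c3d.estimate_contact_points(clusters, d=20.0)
ev = c3d.evaluate_positions(est, gt, axis_xy=spec.center_xy)
print(f"estimated {len(est)} contact points (ground truth: {len(gt)})")
print(f"position error: mean {ev.mean:.3f} px, sd {ev.sd:.3f} px")
```

Output:

```
detections: 595 total, 422 kept after receptacle gating
clusters vs d: {1: 399, 10: 90, 20: 90, 30: 90, 40: 90, 50: 73}
estimated 90 contact points (ground truth: 90)
position error: mean 0.821 px, sd 0.404 px
```

Reading this: the simulated detector fired 595 times; the 173 planted
false positives all fell outside the receptacle mask and were removed. At
d = 1 the 422 surviving 3D points are barely merged (399 clusters,
over-segmentation); across d = 10–40 the count plateaus at exactly the
planted 90 florets; at d = 50 neighbouring florets start merging
(over-grouping, 73 clusters). The plateau value is the estimated floret
count, and the centroids land within a pixel of the true contact points on
average.

The same pipeline runs from the shell (`capitulum3d simulate / filter /
integrate / cluster / sweep / evaluate / align / slice / run`); `capitulum3d
run --config pipeline.yaml out/` executes all stages and writes per-stage
outputs plus a `manifest.json` recording every input, parameter and seed.
Real CT data enters as a multi-page TIFF (or raw + JSON sidecar), external
detections as a CSV of boxes with confidences, and receptacle masks as
binary TIFFs; estimates are written as CSV and ASCII PLY point clouds for
external meshing tools.

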