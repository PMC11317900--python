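"""3D integration and clustering of per-slice contact-point detections.

A contact point has physical extent, so it is detected on several adjacent
slice planes with small positional errors; back-projecting every kept
detection therefore yields a scattered cloud of 3D points per true contact
point.  Group-average (average-linkage) agglomerative clustering with a
distance-threshold termination groups these clouds without knowing their
number: merging proceeds while the smallest inter-cluster group average is
below a threshold ``d`` and stops once it is >= ``d``.  Each cluster's
centroid is the contact-point estimate, and averaging cancels zero-mean
detection jitter (the more supporting slices, the smaller the centroid
error).

Coordinates stay in voxel units throughout; multiply by the voxel size only
when reporting physical distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .detection_eval import Detection
from .radial_slicer import SlicePlane, plane_to_world


@dataclass
class Point3D:
    """A back-projected detection in voxel coordinates."""

    x: float
    y: float
    z: float
    source_slice: str = ""
    source_confidence: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.x, self.y, self.z]).all():
            raise ValueError("coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Cluster:
    """A group of back-projected points with their arithmetic-mean centroid."""

    members: np.ndarray
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        if len(self.members) == 0:
            raise ValueError("cluster must be non-empty")

    @property
    def centroid(self) -> np.ndarray:
        return self.members.mean(axis=0)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ContactPointSet:
    """Cluster centroids as contact-point estimates, one per cluster."""

    estimates: np.ndarray
    threshold_d: float

    def __post_init__(self) -> None:
        self.estimates = np.atleast_2d(np.asarray(self.estimates, dtype=float))

    def __len__(self) -> int:
        return len(self.estimates)


def backproject(det: Detection, plane: SlicePlane) -> Point3D:
    """Place a detection into 3D: the world position of its box centre.

    Box size is irrelevant to the analysis — only the spatial distribution
    of contact points matters — so the symmetric centre is integrated.
    """
    if abs(det.theta_deg - plane.theta_deg) > 1e-9:
        raise ValueError(
            f"detection azimuth {det.theta_deg} != plane azimuth {plane.theta_deg}"
        )
    h, v = det.box.center
    w = plane_to_world(plane, h, v)
    return Point3D(
        float(w[0]), float(w[1]), float(w[2]),
        source_slice=det.slice_id, source_confidence=det.confidence,
    )


def _as_array(points) -> np.ndarray:
    if len(points) and isinstance(points[0], Point3D):
        return np.array([p.xyz for p in points])
    return np.atleast_2d(np.asarray(points, dtype=float))


def group_average(a: Cluster, b: Cluster) -> float:
    """Mean of all |A||B| pairwise Euclidean distances between two clusters."""
    return float(cdist(a.members, b.members).mean())


def agglomerate(points, d: float) -> list[Cluster]:
    """Group-average agglomeration terminated at threshold ``d``.

    Starts from singletons and repeatedly merges the pair of clusters with
    the smallest group-average distance while that minimum is < ``d``;
    stops when the minimum is >= ``d`` or one cluster remains.  Distances
    are updated with the exact average-linkage (Lance-Williams) recurrence,
    so the result equals a naive recompute-from-scratch agglomeration.
    Equal minima are broken by the lexicographically smallest pair of
    cluster-creation indices (singletons 0..n-1 in input order, merged
    clusters numbered onward).
    """
    pts = _as_array(points)
    n = len(pts)
    if n == 0:
        raise ValueError("at least one point is required")
    if d <= 0:
        raise ValueError("threshold d must be positive")
    if n == 1:
        return [Cluster(members=pts, indices=(0,))]

    dist = cdist(pts, pts)
    np.fill_diagonal(dist, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    created = np.arange(n)  # creation index of the cluster in each row
    members: list[list[int]] = [[i] for i in range(n)]
    next_created = n

    while active.sum() > 1:
        sub = np.where(active)[0]
        block = dist[np.ix_(sub, sub)]
        m = block.min()
        if m >= d:
            break
        # tie-break: smallest (older, newer) creation-index pair
        ii, jj = np.where(block == m)
        best = min(
            (tuple(sorted((created[sub[a]], created[sub[b]]))), sub[a], sub[b])
            for a, b in zip(ii, jj)
            if a < b
        )
        i, j = best[1], best[2]
        # average-linkage update: merge j into i
        si, sj = sizes[i], sizes[j]
        new_row = (si * dist[i] + sj * dist[j]) / (si + sj)
        dist[i, :] = new_row
        dist[:, i] = new_row
        dist[i, i] = np.inf
        dist[j, :] = np.inf
        dist[:, j] = np.inf
        sizes[i] = si + sj
        members[i].extend(members[j])
        created[i] = next_created
        next_created += 1
        active[j] = False

    return [
        Cluster(members=pts[members[i]], indices=tuple(members[i]))
        for i in np.where(active)[0]
    ]


def estimate_contact_points(clusters: Sequence[Cluster], d: float) -> ContactPointSet:
    """Contact-point estimates: one cluster centroid per cluster."""
    return ContactPointSet(
        estimates=np.array([c.centroid for c in clusters]), threshold_d=d
    )


def sweep_cluster_counts(points, d_values: Sequence[float]) -> dict[float, int]:
    """Cluster count for each termination threshold (non-increasing in d)."""
    return {float(d): len(agglomerate(points, d)) for d in d_values}


@dataclass
class PositionEvaluation:
    """Per-estimate nearest-ground-truth errors with summary statistics."""

    errors: np.ndarray
    nearest_gt_index: np.ndarray
    axis_distances: np.ndarray | None
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        self.mean = float(self.errors.mean())
        self.sd = float(self.errors.std())  # population sd


def evaluate_positions(
    estimates, gt, axis_xy: tuple[float, float] | None = None
) -> PositionEvaluation:
    """Distance of each estimate to its nearest ground-truth point.

    Also reports each estimate's radial distance from the rotation axis
    (vertical line through ``axis_xy``) when given, for error-vs-radius
    analysis: tangential slice spacing, and hence expected error, grows
    with distance from the axis, while crowding near the apex degrades
    clustering close to it.
    """
    est = estimates.estimates if isinstance(estimates, ContactPointSet) else _as_array(estimates)
    gt = _as_array(gt)
    if len(gt) == 0:
        raise ValueError("ground truth must be non-empty")
    dists, idx = cKDTree(gt).query(est)
    axis_d = None
    if axis_xy is not None:
        axis_d = np.hypot(est[:, 0] - axis_xy[0], est[:, 1] - axis_xy[1])
    return PositionEvaluation(errors=dists, nearest_gt_index=idx, axis_distances=axis_d)


def nearest_floret_distances(points) -> np.ndarray:
    """For each point, the Euclidean distance to its nearest other point."""
    pts = _as_array(points)
    if len(pts) < 2:
        raise ValueError("at least two points are required")
    dists, _ = cKDTree(pts).query(pts, k=2)
    return dists[:, 1]
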