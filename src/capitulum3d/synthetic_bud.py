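"""Synthetic flower buds: receptacle geometry, phyllotaxis, noisy detections.

The generator emulates the geometry the pipeline consumes without any CT
data: a conical or paraboloidal receptacle surface of revolution, contact
points placed phyllotactically on it (Vogel spiral: golden-angle azimuths,
area-uniform sqrt radial spacing — apex-dense, roughly even packing),
per-slice receptacle masks, and detections with in-plane Gaussian jitter,
random misses and floret-region false positives.  False positives are
placed strictly clear of the receptacle mask so the mask-overlap filter's
effect is measurable in isolation.

With all noise parameters at zero the generator reproduces an idealised
setting where slice coordinates of every contact point are known exactly,
which is the regime used for evaluating the slicing and clustering geometry
itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .detection_eval import BBox, Detection, MaskImage
from .radial_slicer import SlicePlane, plane_to_world, world_to_plane
from .volume_io import Volume

GOLDEN_ANGLE_DEG = 137.508


@dataclass
class BudSpec:
    """Parametric receptacle + phyllotaxis specification.

    The receptacle is a surface of revolution ``z(r)`` about the vertical
    axis through ``center_xy``: a cone ``z = apex_z - r / tan(alpha)`` with
    half-angle ``alpha`` (default 45 deg, matching the roughly conical
    receptacle of a late-stage bud) or a paraboloid
    ``z = apex_z - r^2 / curvature``.  ``n_florets`` contact points sit on
    the surface along a Vogel spiral with radial scale ``spiral_constant``
    (default 25 px, which yields nearest-neighbour inter-floret distances of
    roughly 50 px, the spacing observed on real late-stage buds); radii are
    clipped at the rim.  All lengths are in pixels/voxels.
    """

    n_florets: int = 90
    profile: str = "cone"  # "cone" or "paraboloid"
    base_radius_px: float = 400.0
    apex_z: float = 460.0
    cone_half_angle_deg: float = 45.0
    paraboloid_curvature: float = 400.0
    spiral_constant: float | None = None
    center_xy: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_florets < 1:
            raise ValueError("n_florets must be >= 1")
        if self.base_radius_px <= 0:
            raise ValueError("base_radius_px must be positive")
        if self.profile not in {"cone", "paraboloid"}:
            raise ValueError(f"unknown profile {self.profile!r}")

    @property
    def radial_scale(self) -> float:
        return 25.0 if self.spiral_constant is None else self.spiral_constant

    def surface_z(self, r) -> np.ndarray:
        """Receptacle height z(r) at radial distance r from the axis."""
        r = np.asarray(r, dtype=float)
        if self.profile == "cone":
            return self.apex_z - r / math.tan(math.radians(self.cone_half_angle_deg))
        return self.apex_z - r**2 / self.paraboloid_curvature

    @property
    def base_z(self) -> float:
        """Height of the receptacle base (surface height at the rim)."""
        return float(self.surface_z(self.base_radius_px))


@dataclass
class NoiseSpec:
    """Detection-noise model for the simulated detector.

    ``capture_halfwidth_px`` models the physical extent of a contact point:
    it appears on every slice plane passing within that perpendicular
    distance, and hence on more planes the closer it sits to the axis.
    """

    jitter_sigma_px: float = 1.0
    p_miss: float = 0.0
    fp_rate: float = 0.0
    capture_halfwidth_px: float = 3.0
    box_size_px: float = 8.0

    def __post_init__(self) -> None:
        if min(self.jitter_sigma_px, self.fp_rate, self.capture_halfwidth_px, self.box_size_px) < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (0.0 <= self.p_miss <= 1.0):
            raise ValueError("p_miss must lie in [0, 1]")


def make_bud(spec: BudSpec) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Ground-truth contact points on the receptacle surface.

    Point ``k`` (k = 1..n) sits at azimuth ``k * 137.508 deg`` and radius
    ``radial_scale * sqrt(k)`` clipped to the receptacle rim, projected onto
    the profile.  Deterministic given the spec.  Returns the (n, 3) point
    array (world coordinates, axis through ``center_xy``) and the profile
    function ``z(r)``.
    """
    k = np.arange(1, spec.n_florets + 1, dtype=float)
    az = np.deg2rad(k * GOLDEN_ANGLE_DEG)
    r = np.minimum(spec.radial_scale * np.sqrt(k), spec.base_radius_px)
    cx, cy = spec.center_xy
    pts = np.column_stack([cx + r * np.cos(az), cy + r * np.sin(az), spec.surface_z(r)])
    return pts, spec.surface_z


def render_mask(spec: BudSpec, plane: SlicePlane) -> MaskImage:
    """Receptacle mask on one slice plane.

    A pixel at signed radius ``r`` and height ``v`` is receptacle iff
    ``|r| <= base_radius`` and ``base_z <= v <= z(|r|)``; by rotational
    symmetry the mask is the same on every plane.
    """
    h = np.arange(plane.width, dtype=float)[:, None]
    v = np.arange(plane.height, dtype=float)[None, :]
    r = np.abs(h - plane.axis_column)
    inside = (r <= spec.base_radius_px) & (v >= spec.base_z) & (v <= spec.surface_z(r))
    return MaskImage(pixels=inside, theta_deg=plane.theta_deg, slice_id=plane.slice_id)


def render_masks(spec: BudSpec, planes: Sequence[SlicePlane]) -> list[MaskImage]:
    """Receptacle masks for a set of slice planes."""
    return [render_mask(spec, p) for p in planes]


def render_volume(spec: BudSpec, shape: tuple[int, int, int], voxel_size_um: float = 2.75) -> Volume:
    """Voxelise the receptacle as a bright solid on a dark background.

    Intended for exercising the reslicer end-to-end; photometric realism is
    out of scope.  The spec's ``center_xy`` is ignored — the solid is
    centred on the grid, matching the reslicer's rotation centre.
    """
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    r = np.hypot(x - cx, y - cy)
    inside = (r <= spec.base_radius_px) & (z >= spec.base_z) & (z <= spec.surface_z(r))
    return Volume((inside * np.uint8(255)), voxel_size_um, axis_aligned=True)


def _fp_candidate_pixels(mask: MaskImage, box_size_px: float) -> np.ndarray:
    """Integer pixel centres whose whole box stays clear of the mask."""
    half = int(math.ceil(box_size_px / 2.0))
    footprint = np.ones((2 * half + 1, 2 * half + 1), dtype=bool)
    forbidden = ndimage.binary_dilation(mask.pixels, structure=footprint)
    # keep a margin so the emitted box stays inside the image
    forbidden[:half, :] = True
    forbidden[-half:, :] = True
    forbidden[:, :half] = True
    forbidden[:, -half:] = True
    return np.argwhere(~forbidden)


def simulate_detections(
    gt_points: np.ndarray,
    planes: Sequence[SlicePlane],
    noise: NoiseSpec,
    receptacle_masks: Sequence[MaskImage] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Detection]:
    """Emit noisy per-slice detections for the ground-truth contact points.

    For every plane and every contact point within ``capture_halfwidth_px``
    of it: with probability ``1 - p_miss``, a box of side ``box_size_px``
    centred on the point's in-plane projection plus 2D Gaussian jitter.
    Additionally Poisson(``fp_rate``) false positives per slice, placed
    uniformly over pixel centres whose whole box lies off the receptacle
    mask (``receptacle_masks`` is required when ``fp_rate > 0``).  True
    detections get confidences in [0.6, 1.0), false positives in
    [0.05, 0.6).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if noise.fp_rate > 0 and receptacle_masks is None:
        raise ValueError("receptacle_masks are required when fp_rate > 0")
    gt_points = np.atleast_2d(np.asarray(gt_points, dtype=float))
    half = noise.box_size_px / 2.0
    dets: list[Detection] = []
    for i, plane in enumerate(planes):
        h, v, off = world_to_plane(plane, gt_points)
        for hk, vk, offk in zip(h, v, off):
            if abs(offk) > noise.capture_halfwidth_px:
                continue
            if noise.p_miss > 0 and rng.random() < noise.p_miss:
                continue
            jx, jy = rng.normal(0.0, noise.jitter_sigma_px, size=2) if noise.jitter_sigma_px > 0 else (0.0, 0.0)
            cxp, cyp = hk + jx, vk + jy
            dets.append(
                Detection(
                    box=BBox(cxp - half, cyp - half, cxp + half, cyp + half),
                    confidence=float(rng.uniform(0.6, 1.0)),
                    theta_deg=plane.theta_deg,
                    slice_id=plane.slice_id,
                )
            )
        if noise.fp_rate > 0:
            n_fp = rng.poisson(noise.fp_rate)
            if n_fp:
                cand = _fp_candidate_pixels(receptacle_masks[i], noise.box_size_px)
                for j in rng.integers(0, len(cand), size=n_fp):
                    fh, fv = cand[j]
                    dets.append(
                        Detection(
                            box=BBox(fh - half, fv - half, fh + half, fv + half),
                            confidence=float(rng.uniform(0.05, 0.6)),
                            theta_deg=plane.theta_deg,
                            slice_id=plane.slice_id,
                        )
                    )
    return dets


def jittered_centroid_error(
    n_slices: int,
    jitter_sigma_px: float,
    radius_px: float,
    z: float,
    rng: np.random.Generator,
    width: int = 512,
    height: int = 512,
) -> float:
    """Centroid error for one planted point detected on ``n_slices`` planes.

    The point sits at radius ``radius_px``, azimuth 90 deg; it is detected
    (with i.i.d. zero-mean Gaussian jitter) on ``n_slices`` planes spread
    evenly within +-0.5 deg of its azimuth, back-projected, and averaged.
    Returns the Euclidean distance of the centroid from the truth — the
    quantity that shrinks with ``n_slices`` as the jitter averages out.
    """
    truth = np.array([0.0, radius_px, z])
    thetas = np.linspace(89.5, 90.5, n_slices) if n_slices > 1 else np.array([90.0])
    pts = []
    for t in thetas:
        plane = SlicePlane(theta_deg=t, center_xy=(0.0, 0.0), width=width, height=height)
        h, v, _ = world_to_plane(plane, truth)
        jx, jy = rng.normal(0.0, jitter_sigma_px, size=2)
        pts.append(plane_to_world(plane, float(h) + jx, float(v) + jy))
    centroid = np.mean(pts, axis=0)
    return float(np.linalg.norm(centroid - truth))
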