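"""Loading, saving and axis-alignment of CT volumes.

A :class:`Volume` is a 3D scalar grid indexed ``(x, y, z)`` with an isotropic
voxel size in micrometres.  Multi-page TIFF stacks map page index to ``z``
(so a stack of ``Nz`` pages of ``Ny x Nx`` frames becomes a grid of shape
``(Nx, Ny, Nz)``).  Raw binary volumes carry a JSON sidecar naming shape,
dtype and voxel size, because TIFF alone has no guaranteed voxel-size tag.

Buds are imaged with their rotation axis roughly along ``z``; tilted samples
are brought into that convention by :func:`rotate_volume_to_axis`, which
rigidly maps a user-supplied axis estimate onto the ``z`` grid axis through
the volume centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage


@dataclass
class Volume:
    """A 3D grayscale grid with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (Nx, Ny, Nz)
        Scalar voxel values, indexed ``(x, y, z)``.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres; must be positive.
    axis_aligned : bool
        True when the bud rotation axis coincides with the ``z`` grid axis.
    """

    data: np.ndarray
    voxel_size_um: float
    axis_aligned: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def center(self) -> np.ndarray:
        """Continuous grid centre ((Nx-1)/2, (Ny-1)/2, (Nz-1)/2), voxel units."""
        return (np.asarray(self.data.shape, dtype=float) - 1.0) / 2.0

    def mean_value(self) -> float:
        """Mean of all voxel values; used as the out-of-bounds fill value."""
        return float(self.data.mean())


@dataclass
class AxisEstimate:
    """A rotation-axis estimate: a point the axis passes through and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.point.shape != (3,) or self.direction.shape != (3,):
            raise ValueError("point and direction must be 3-vectors")
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length within 1e-9, norm={n}")

    @classmethod
    def from_vector(cls, point, direction) -> "AxisEstimate":
        """Build an estimate from an arbitrary (non-zero) direction vector."""
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction has zero length")
        return cls(np.asarray(point, dtype=float), d / n)


def load_volume(path, voxel_size_um: float | None = None, axis_aligned: bool = True) -> Volume:
    """Load a volume from a multi-page TIFF stack or raw binary + JSON sidecar.

    TIFF page index maps to ``z``.  For raw binary, ``path`` may point either
    at the ``.raw`` file or at its ``.json`` sidecar; the sidecar must name
    ``shape`` (Nx, Ny, Nz), ``dtype`` and ``voxel_size_um``.  An explicit
    ``voxel_size_um`` argument overrides the sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) != 1:
                raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
            stack = tf.asarray()
        if stack.ndim == 2:  # single page
            stack = stack[None]
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required for TIFF input")
        # pages (z, y, x) -> grid (x, y, z)
        return Volume(np.ascontiguousarray(stack.T), float(voxel_size_um), axis_aligned)
    sidecar = path if path.suffix == ".json" else path.with_suffix(".json")
    raw = path.with_suffix(".raw") if path.suffix == ".json" else path
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    shape = tuple(int(s) for s in meta["shape"])
    data = np.fromfile(raw, dtype=np.dtype(meta["dtype"])).reshape(shape)
    vs = float(voxel_size_um if voxel_size_um is not None else meta["voxel_size_um"])
    return Volume(data, vs, axis_aligned)


def save_volume(v: Volume, path) -> None:
    """Save as multi-page TIFF (page index = z) or raw binary + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, np.ascontiguousarray(v.data.T), photometric="minisblack")
        return
    raw = path if path.suffix == ".raw" else path.with_suffix(".raw")
    np.ascontiguousarray(v.data).tofile(raw)
    raw.with_suffix(".json").write_text(
        json.dumps(
            {"shape": list(v.data.shape), "dtype": v.data.dtype.name, "voxel_size_um": v.voxel_size_um}
        )
    )


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ direction = z (minimal-angle rotation)."""
    u = np.asarray(direction, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        raise ValueError("axis direction antiparallel to z: rotation is degenerate")
    k = np.cross(u, z)
    s = np.linalg.norm(k)
    k = k / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kx + (1.0 - c) * (kx @ kx)


def rotate_volume_to_axis(v: Volume, axis: AxisEstimate) -> Volume:
    """Resample so the estimated bud axis maps onto the z grid axis.

    The rigid map sends the axis line to the vertical line through the grid
    centre; the axis point closest to the centre maps exactly onto the
    centre.  Resampling is nearest-neighbour; voxels whose preimage falls
    outside the source grid are filled with the mean of all source voxel
    values, preserving the intensity statistics of the stack.
    """
    if np.linalg.norm(axis.direction) == 0:
        raise ValueError("axis direction has zero length")
    rot = _rotation_to_z(axis.direction)
    c = v.center
    # point on the axis closest to the grid centre: anchor of the rigid map
    a0 = axis.point + axis.direction * np.dot(c - axis.point, axis.direction)
    # affine_transform: input_coord = matrix @ output_coord + offset
    matrix = rot.T
    offset = a0 - matrix @ c
    out = ndimage.affine_transform(
        v.data.astype(float, copy=False),
        matrix,
        offset=offset,
        order=0,
        mode="constant",
        cval=v.mean_value(),
    )
    if not np.issubdtype(v.data.dtype, np.floating):
        out = np.rint(out).astype(v.data.dtype)
    return Volume(out, v.voxel_size_um, axis_aligned=True)
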