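"""On-disk formats: detection CSVs, point CSVs, masks, slices, PLY, manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .detection_eval import BBox, Detection, MaskImage
from .radial_slicer import SliceImage, SlicePlane

DETECTION_COLUMNS = ["slice_id", "theta_deg", "x_min", "y_min", "x_max", "y_max", "confidence"]


def save_detections(path, dets: Sequence[Detection], kept: Sequence[bool] | None = None) -> None:
    rows = [
        {
            "slice_id": d.slice_id,
            "theta_deg": d.theta_deg,
            "x_min": d.box.x_min,
            "y_min": d.box.y_min,
            "x_max": d.box.x_max,
            "y_max": d.box.y_max,
            "confidence": d.confidence,
        }
        for d in dets
    ]
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    if kept is not None:
        df["kept"] = list(kept)
    df.to_csv(path, index=False)


def load_detections(path, kept_only: bool = False) -> list[Detection]:
    df = pd.read_csv(path, dtype={"slice_id": str})
    if kept_only and "kept" in df.columns:
        df = df[df["kept"]]
    return [
        Detection(
            box=BBox(r.x_min, r.y_min, r.x_max, r.y_max),
            confidence=float(r.confidence),
            theta_deg=float(r.theta_deg),
            slice_id=str(r.slice_id),
        )
        for r in df.itertuples()
    ]


def save_points(path, points: np.ndarray, cluster_ids: Sequence[int] | None = None) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    df = pd.DataFrame(pts, columns=["x", "y", "z"])
    if cluster_ids is not None:
        df["cluster_id"] = list(cluster_ids)
    df.to_csv(path, index=False)


def load_points(path) -> np.ndarray:
    return pd.read_csv(path)[["x", "y", "z"]].to_numpy(dtype=float)


def save_ply(path, points: np.ndarray) -> None:
    """ASCII PLY point cloud, for external meshing/rendering tools."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {len(pts)}\n")
        f.write("property float x\nproperty float y\nproperty float z\nend_header\n")
        for x, y, z in pts:
            f.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def save_mask(path, mask: MaskImage) -> None:
    # stored row-major (height, width) as standard image orientation
    tifffile.imwrite(path, (mask.pixels.T * np.uint8(255)), photometric="minisblack")


def load_mask(path, theta_deg: float = 0.0, slice_id: str = "") -> MaskImage:
    arr = tifffile.imread(path)
    return MaskImage(pixels=arr.T > 0, theta_deg=theta_deg, slice_id=slice_id)


def save_slices(outdir, slices: Sequence[SliceImage]) -> Path:
    """Write numbered slice TIFFs plus a JSON manifest of plane geometry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(slices):
        name = f"slice_{i:04d}.tif"
        tifffile.imwrite(outdir / name, s.pixels.T.astype(np.float32), photometric="minisblack")
        manifest.append(
            {
                "file": name,
                "slice_id": s.plane.slice_id or f"s{i:04d}",
                "theta_deg": s.plane.theta_deg,
                "center_x": s.plane.center_xy[0],
                "center_y": s.plane.center_xy[1],
                "width": s.plane.width,
                "height": s.plane.height,
                "fill_value": s.fill_value,
            }
        )
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def save_planes(path, planes: Sequence[SlicePlane]) -> None:
    entries = [
        {
            "slice_id": p.slice_id,
            "theta_deg": p.theta_deg,
            "center_x": p.center_xy[0],
            "center_y": p.center_xy[1],
            "width": p.width,
            "height": p.height,
        }
        for p in planes
    ]
    Path(path).write_text(json.dumps(entries, indent=1))


def load_planes(path) -> list[SlicePlane]:
    entries = json.loads(Path(path).read_text())
    return [
        SlicePlane(
            theta_deg=float(e["theta_deg"]),
            center_xy=(float(e["center_x"]), float(e["center_y"])),
            width=int(e["width"]),
            height=int(e["height"]),
            slice_id=str(e["slice_id"]),
        )
        for e in entries
    ]
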