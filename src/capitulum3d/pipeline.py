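"""Staged pipeline orchestration: simulate/slice -> filter -> integrate -> cluster -> evaluate.

Each stage writes its outputs and parameters into its own subdirectory of
the run directory, and the top-level ``manifest.json`` records every input,
parameter and seed, so any stage can be re-run reproducibly from what the
manifest names.  Detection is external in production use (any detector that
emits the detection CSV format works); the synthetic branch generates
detections internally so the whole pipeline runs without CT data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import io_formats
from .fp_filter import filter_detections
from .integrate_cluster import (
    agglomerate,
    backproject,
    estimate_contact_points,
    evaluate_positions,
    nearest_floret_distances,
    sweep_cluster_counts,
)
from .radial_slicer import generate_planes, generate_slices
from .synthetic_bud import BudSpec, NoiseSpec, make_bud, render_masks, simulate_detections
from .volume_io import AxisEstimate, load_volume, rotate_volume_to_axis

DEFAULT_D_VALUES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


def _masks_by_slice(masks):
    return {m.slice_id: m for m in masks}


def run_pipeline(config: dict, outdir, seed: int | None = None) -> Path:
    """Execute the full pipeline described by ``config``; returns the run dir.

    ``config`` must name either a synthetic ``bud`` section or a ``volume``
    path (with ``voxel_size_um``); validation happens before any work.
    Synthetic runs are pure functions of the config and seed.
    """
    if "bud" not in config and "volume" not in config:
        raise ConfigError("config must name either a 'bud' spec or a 'volume' path")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    interval = float(config.get("interval_deg", 1.0))
    d_values = [float(d) for d in config.get("d_values", DEFAULT_D_VALUES)]

    manifest: dict = {"seed": seed, "interval_deg": interval, "d_values": d_values,
                      "version": _pkg_version(), "stages": {}}

    if "bud" in config:
        planes, gt, dets, masks = _stage_simulate(config, outdir, seed, interval, manifest)
    else:
        planes, gt, dets, masks = _stage_volume(config, outdir, interval, manifest)

    if dets is None:  # volume run without external detections: stop after slicing
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return outdir

    # filter
    fdir = outdir / "filter"
    fdir.mkdir(exist_ok=True)
    if masks:
        by_slice = _masks_by_slice(masks)
        kept_flags = []
        kept = []
        for d in dets:
            k, _ = filter_detections([d], by_slice[d.slice_id])
            kept_flags.append(bool(k))
            if k:
                kept.append(d)
    else:
        kept_flags = [True] * len(dets)
        kept = list(dets)
    io_formats.save_detections(fdir / "detections.csv", dets, kept=kept_flags)
    manifest["stages"]["filter"] = {"n_in": len(dets), "n_kept": len(kept)}

    # integrate
    idir = outdir / "integrate"
    idir.mkdir(exist_ok=True)
    plane_by_id = {p.slice_id: p for p in planes}
    points = np.array([backproject(d, plane_by_id[d.slice_id]).xyz for d in kept])
    io_formats.save_points(idir / "points.csv", points)
    manifest["stages"]["integrate"] = {"n_points": len(points)}

    # cluster: threshold sweep + estimation at d_estimate
    cdir = outdir / "cluster"
    cdir.mkdir(exist_ok=True)
    counts = sweep_cluster_counts(points, d_values)
    with open(cdir / "cluster_counts.csv", "w") as f:
        f.write("d,n_clusters\n")
        for d in d_values:
            f.write(f"{d},{counts[d]}\n")
    d_est = config.get("d_estimate")
    if d_est is None and gt is not None and len(gt) >= 2:
        d_est = float(nearest_floret_distances(gt).min() / 2.0)
    if d_est is None:
        d_est = d_values[-1]
    clusters = agglomerate(points, float(d_est))
    cps = estimate_contact_points(clusters, float(d_est))
    cluster_ids = np.empty(len(points), dtype=int)
    for ci, c in enumerate(clusters):
        cluster_ids[list(c.indices)] = ci
    io_formats.save_points(cdir / "points_labeled.csv", points, cluster_ids=cluster_ids)
    io_formats.save_points(cdir / "estimates.csv", cps.estimates)
    io_formats.save_ply(cdir / "estimates.ply", cps.estimates)
    manifest["stages"]["cluster"] = {
        "counts": {str(d): counts[d] for d in d_values},
        "d_estimate": float(d_est),
        "n_estimates": len(cps),
    }

    # evaluate against ground truth when available
    if gt is not None:
        edir = outdir / "evaluate"
        edir.mkdir(exist_ok=True)
        center = config.get("bud", {}).get("center_xy", (0.0, 0.0))
        ev = evaluate_positions(cps, gt, axis_xy=tuple(center))
        summary = {
            "n_estimates": len(cps),
            "n_ground_truth": len(gt),
            "position_error_mean": ev.mean,
            "position_error_sd": ev.sd,
        }
        if len(cps) >= 2 and len(gt) >= 2:
            nn_est = nearest_floret_distances(cps.estimates)
            nn_gt = nearest_floret_distances(gt)
            nn_err = np.abs(nn_est - nn_gt[ev.nearest_gt_index])
            summary["nn_distance_error_mean"] = float(nn_err.mean())
            summary["nn_distance_error_sd"] = float(nn_err.std())
        (edir / "summary.json").write_text(json.dumps(summary, indent=1))
        try:
            from .plotting import plot_error_vs_axis

            plot_error_vs_axis(ev, edir / "error_vs_axis.png")
        except Exception:
            pass  # plotting is diagnostic only
        manifest["stages"]["evaluate"] = summary

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _pkg_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("capitulum3d")
    except PackageNotFoundError:
        return "unknown"


def _stage_simulate(config, outdir, seed, interval, manifest):
    sdir = outdir / "simulate"
    sdir.mkdir(exist_ok=True)
    bud_cfg = dict(config["bud"])
    bud_cfg.setdefault("seed", seed)
    if "center_xy" in bud_cfg:
        bud_cfg["center_xy"] = tuple(bud_cfg["center_xy"])
    spec = BudSpec(**bud_cfg)
    noise = NoiseSpec(**config.get("noise", {}))
    img = config.get("image", {})
    width = int(img.get("width", 2 * int(spec.base_radius_px) + 50))
    height = int(img.get("height", int(spec.apex_z) + 60))
    planes = generate_planes(interval, spec.center_xy, width, height)
    gt, _ = make_bud(spec)
    masks = render_masks(spec, planes) if (noise.fp_rate > 0 or config.get("render_masks")) else []
    rng = np.random.default_rng(seed)
    dets = simulate_detections(gt, planes, noise, receptacle_masks=masks or None, rng=rng)
    io_formats.save_points(sdir / "gt_points.csv", gt)
    io_formats.save_detections(sdir / "detections.csv", dets)
    io_formats.save_planes(sdir / "planes.json", planes)
    manifest["stages"]["simulate"] = {
        "bud": dataclasses.asdict(spec),
        "noise": dataclasses.asdict(noise),
        "n_planes": len(planes),
        "n_gt": len(gt),
        "n_detections": len(dets),
    }
    return planes, gt, dets, masks


def _stage_volume(config, outdir, interval, manifest):
    vdir = outdir / "slices"
    vol = load_volume(config["volume"], voxel_size_um=config.get("voxel_size_um"))
    if "axis" in config:
        ax = config["axis"]
        vol = rotate_volume_to_axis(
            vol, AxisEstimate.from_vector(ax["point"], ax["direction"])
        )
    slices = generate_slices(vol, interval)
    io_formats.save_slices(vdir, slices)
    planes = [s.plane for s in slices]
    for i, p in enumerate(planes):
        planes[i] = dataclasses.replace(p, slice_id=f"s{i:04d}")
    manifest["stages"]["slice"] = {"volume": str(config["volume"]), "n_slices": len(slices)}
    dets = None
    if "detections" in config:
        dets = io_formats.load_detections(config["detections"])
    masks = []
    if "masks" in config:
        mdir = Path(config["masks"])
        for p in planes:
            mpath = mdir / f"mask_{p.slice_id}.tif"
            if mpath.exists():
                masks.append(io_formats.load_mask(mpath, theta_deg=p.theta_deg, slice_id=p.slice_id))
    gt = io_formats.load_points(config["ground_truth"]) if "ground_truth" in config else None
    return planes, gt, dets, masks
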