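"""On-disk formats: fiber trace tables, MRC volumes, context configs.

Three trace-table dialects are supported:

``xyz_csv``
    CSV with header ``trace_id,point_index,x,y,z`` (coordinates in nm).

``point_segment_tsv``
    Two tab-separated sections modelled on tracing-software exports: a
    ``[points]`` section with columns ``point_id  x  y  z`` and a
    ``[segments]`` section with columns ``segment_id  point_ids`` where
    ``point_ids`` is a comma-separated ordered list of point ids.

``imod_model_text``
    Whitespace-delimited point listing with columns
    ``object contour x y z``; each (object, contour) pair becomes one
    trace.

Coordinates on disk are nm unless a ``scale`` (nm per file unit) is
given, e.g. the voxel size for pixel-unit files.  All readers reject
non-finite coordinates with a diagnostic naming the line.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path

import numpy as np
import yaml

from . import mrc
from .datatypes import FiberTrace, TomogramContext, TraceSet, DensityVolume

DIALECTS = ("point_segment_tsv", "xyz_csv", "imod_model_text")


class TraceTableError(ValueError):
    """Malformed trace table; message names the offending line."""


def _check_finite(vals: list[float], path: Path, lineno: int) -> None:
    if not all(math.isfinite(v) for v in vals):
        raise TraceTableError(f"{path}:{lineno}: non-finite coordinate in row {vals}")


def _build_traceset(
    contours: dict[int, list[tuple[float, float, float]]],
    scale: float,
    provenance: str,
) -> TraceSet:
    traces = []
    skipped = 0
    for cid in sorted(contours):
        pts = np.asarray(contours[cid], dtype=float) * scale
        # drop exact consecutive duplicates rather than failing the trace
        if pts.shape[0] >= 2:
            keep = np.ones(pts.shape[0], dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
            pts = pts[keep]
        if pts.shape[0] < 2:
            skipped += 1
            continue
        traces.append(FiberTrace(cid, pts))
    if skipped:
        provenance += f" [skipped {skipped} contour(s) with <2 points]"
    return TraceSet(traces, provenance=provenance)


def _read_xyz_csv(path: Path, scale: float) -> TraceSet:
    contours: dict[int, list[tuple[float, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "trace_id":
                continue
            if len(row) != 5:
                raise TraceTableError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            try:
                tid = int(row[0])
                xyz = [float(v) for v in row[2:5]]
            except ValueError as exc:
                raise TraceTableError(f"{path}:{lineno}: {exc}") from None
            _check_finite(xyz, path, lineno)
            contours.setdefault(tid, []).append(tuple(xyz))
    return _build_traceset(contours, scale, f"xyz_csv:{path.name}")


def _read_point_segment_tsv(path: Path, scale: float) -> TraceSet:
    points: dict[int, tuple[float, float, float]] = {}
    segments: dict[int, list[int]] = {}
    section = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower() in ("[points]", "[segments]"):
                section = line.lower().strip("[]")
                continue
            cols = line.split("\t")
            if cols[0] in ("point_id", "segment_id"):
                continue
            if section == "points":
                if len(cols) != 4:
                    raise TraceTableError(
                        f"{path}:{lineno}: point row needs 4 columns, got {len(cols)}"
                    )
                try:
                    pid = int(cols[0])
                    xyz = [float(v) for v in cols[1:4]]
                except ValueError as exc:
                    raise TraceTableError(f"{path}:{lineno}: {exc}") from None
                _check_finite(xyz, path, lineno)
                points[pid] = tuple(xyz)
            elif section == "segments":
                if len(cols) != 2:
                    raise TraceTableError(
                        f"{path}:{lineno}: segment row needs 2 columns, got {len(cols)}"
                    )
                try:
                    sid = int(cols[0])
                    pids = [int(v) for v in cols[1].split(",") if v != ""]
                except ValueError as exc:
                    raise TraceTableError(f"{path}:{lineno}: {exc}") from None
                segments[sid] = pids
            else:
                raise TraceTableError(f"{path}:{lineno}: data before a [points]/[segments] header")
    contours: dict[int, list[tuple[float, float, float]]] = {}
    for sid, pids in segments.items():
        missing = [p for p in pids if p not in points]
        if missing:
            raise TraceTableError(f"{path}: segment {sid} references unknown point ids {missing}")
        contours[sid] = [points[p] for p in pids]
    return _build_traceset(contours, scale, f"point_segment_tsv:{path.name}")


def _read_imod_model_text(path: Path, scale: float) -> TraceSet:
    contours: dict[int, list[tuple[float, float, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 5:
                raise TraceTableError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
            try:
                obj, cont = int(cols[0]), int(cols[1])
                xyz = [float(v) for v in cols[2:5]]
            except ValueError as exc:
                raise TraceTableError(f"{path}:{lineno}: {exc}") from None
            _check_finite(xyz, path, lineno)
            # flatten (object, contour) into one id space
            contours.setdefault(obj * 100000 + cont, []).append(tuple(xyz))
    return _build_traceset(contours, scale, f"imod_model_text:{path.name}")


def read_trace_table(
    path: str | Path, dialect: str = "xyz_csv", scale: float = 1.0
) -> TraceSet:
    """Read a trace table into a TraceSet.

    Parameters
    ----------
    path : file to read
    dialect : one of ``point_segment_tsv``, ``xyz_csv``, ``imod_model_text``
    scale : nm per file coordinate unit (e.g. voxel size for pixel files)
    """
    path = Path(path)
    if dialect == "xyz_csv":
        return _read_xyz_csv(path, scale)
    if dialect == "point_segment_tsv":
        return _read_point_segment_tsv(path, scale)
    if dialect == "imod_model_text":
        return _read_imod_model_text(path, scale)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_trace_table(ts: TraceSet, path: str | Path, dialect: str = "xyz_csv") -> None:
    """Write a TraceSet in the named dialect (coordinates in nm, %.6f)."""
    path = Path(path)
    if dialect == "xyz_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trace_id", "point_index", "x", "y", "z"])
            for t in ts.traces:
                for i, (x, y, z) in enumerate(t.points):
                    w.writerow([t.trace_id, i, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])
    elif dialect == "point_segment_tsv":
        with open(path, "w") as fh:
            if ts.provenance:
                fh.write(f"# {ts.provenance}\n")
            fh.write("[points]\npoint_id\tx\ty\tz\n")
            pid = 0
            seg_rows = []
            for t in ts.traces:
                pids = []
                for x, y, z in t.points:
                    fh.write(f"{pid}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
                    pids.append(pid)
                    pid += 1
                seg_rows.append((t.trace_id, pids))
            fh.write("[segments]\nsegment_id\tpoint_ids\n")
            for sid, pids in seg_rows:
                fh.write(f"{sid}\t{','.join(map(str, pids))}\n")
    elif dialect == "imod_model_text":
        with open(path, "w") as fh:
            fh.write("# object contour x y z\n")
            for t in ts.traces:
                for x, y, z in t.points:
                    fh.write(f"1 {t.trace_id} {x:.6f} {y:.6f} {z:.6f}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC2014 volume."""
    return mrc.read_mrc(path)


def write_volume(vol: DensityVolume, path: str | Path, mode: int | None = None) -> None:
    """Write a DensityVolume as MRC2014."""
    mrc.write_mrc(vol, path, mode=mode)


_CONTEXT_KEYS = (
    "milling_angle_deg",
    "voxel_size_nm",
    "cell_axis_angle_deg",
    "projected_distance_um",
    "scale_number",
    "treatment",
)


def load_context(config_path: str | Path) -> TomogramContext:
    """Load a per-tomogram context from a YAML or JSON config file.

    Required keys: milling_angle_deg, voxel_size_nm, cell_axis_angle_deg
    (angle between the tomogram x-axis and the cell long axis, degrees),
    projected_distance_um, scale_number, treatment.  Optional:
    ``depth_mode`` ("tan", default, or "sin").
    """
    config_path = Path(config_path)
    text = config_path.read_text()
    cfg = json.loads(text) if config_path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{config_path}: config must be a mapping")
    missing = [k for k in _CONTEXT_KEYS if k not in cfg]
    if missing:
        raise KeyError(f"{config_path}: missing required keys: {', '.join(missing)}")
    beta = math.radians(float(cfg["cell_axis_angle_deg"]))
    axis = (math.cos(beta), math.sin(beta))
    from .geometry import tomogram_depth

    depth = tomogram_depth(
        float(cfg["projected_distance_um"]),
        float(cfg["milling_angle_deg"]),
        mode=cfg.get("depth_mode", "tan"),
    )
    return TomogramContext(
        milling_angle_deg=float(cfg["milling_angle_deg"]),
        voxel_size_nm=float(cfg["voxel_size_nm"]),
        cell_axis=axis,
        projected_distance_um=float(cfg["projected_distance_um"]),
        scale_number=int(cfg["scale_number"]),
        treatment=str(cfg["treatment"]),
        depth_um=depth,
    )
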