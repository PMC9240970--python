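"""Per-fiber geometric analysis.

The canonical stage order for a tomogram's trace set is::

    read -> filter_out_of_plane -> apply_milling_rotation
         -> trim_vertical_artifacts -> canonicalize -> resample -> metrics

The out-of-plane filter runs in the unrotated (as-reconstructed) frame
by default, before the milling-tilt correction; both orders are exposed
via :func:`process_traceset`.

Statistics per fiber: polyline length, mean Menger curvature radius
(circumradius of consecutive point triples), mean local slope dz/dxy
after direction canonicalization, mean z-height, and the clockwise
angle between the fiber's xy direction and the cell long axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .datatypes import FiberMetrics, FiberTrace, TraceSet, replace_traces

DEGENERATE_TRIANGLE_AREA_NM2 = 1e-6


# ---------------------------------------------------------------------------
# rigid transforms and filters


def apply_milling_rotation(ts: TraceSet, alpha_deg: float) -> TraceSet:
    """Rotate all traces rigidly about the y-axis by the milling angle.

    Sign convention: positive alpha tilts the +x axis toward -z
    (x' = x cos a + z sin a; z' = -x sin a + z cos a), so the lamella
    leading edge stays shallow and depth increases along the milled face.
    """
    a = math.radians(alpha_deg)
    c, s = math.cos(a), math.sin(a)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    def fn(pts: np.ndarray) -> np.ndarray:
        return pts @ rot.T

    return replace_traces(ts, [FiberTrace(t.trace_id, fn(t.points)) for t in ts.traces])


def out_of_plane_angle_deg(trace: FiberTrace) -> float:
    """Inclination of the end-to-end chord relative to the xy-plane, degrees.

    Returns 90 for a zero-length chord (closed contour), which the filter
    treats as removable.
    """
    chord = trace.points[-1] - trace.points[0]
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 90.0
    return math.degrees(math.asin(min(1.0, abs(chord[2]) / norm)))


@dataclass
class RejectionReport:
    """Ids and diagnostics for traces removed by a filter stage."""

    stage: str
    removed: list[tuple[int, float]] = field(default_factory=list)  # (trace_id, value)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_out_of_plane(
    ts: TraceSet, theta_max_deg: float = 70.0
) -> tuple[TraceSet, RejectionReport]:
    """Remove traces whose end-to-end chord is steeper than theta_max.

    Steep contours in reconstructed tomograms are reconstruction
    artifacts, not fibers.
    """
    report = RejectionReport(stage="out_of_plane")
    kept = []
    for t in ts.traces:
        ang = out_of_plane_angle_deg(t)
        if ang > theta_max_deg:
            report.removed.append((t.trace_id, ang))
        else:
            kept.append(t)
    note = f"out_of_plane>{theta_max_deg}deg removed {report.n_removed}"
    return ts.with_traces(kept, note), report


def orientation_tensor(trace: FiberTrace) -> np.ndarray:
    """Second-moment tensor of the unit tangent vectors, (3, 3)."""
    seg = np.diff(trace.points, axis=0)
    tang = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    return tang.T @ tang / tang.shape[0]


def trim_vertical_artifacts(
    ts: TraceSet,
    zz_max: float = 0.8,
    xz_abs_max: float | None = None,
) -> tuple[TraceSet, RejectionReport]:
    """Remove traces dominated by vertical (z-parallel) runs.

    A trace is removed when the ZZ component of its tangent
    second-moment tensor exceeds ``zz_max``, or (if configured) when the
    |XZ| component exceeds ``xz_abs_max``.  Punctate tomogram signal
    tends to propagate into artifactual vertical lines with ZZ near 1.
    """
    report = RejectionReport(stage="vertical_artifact")
    kept = []
    for t in ts.traces:
        m = orientation_tensor(t)
        bad = m[2, 2] > zz_max or (xz_abs_max is not None and abs(m[0, 2]) > xz_abs_max)
        if bad:
            report.removed.append((t.trace_id, float(m[2, 2])))
        else:
            kept.append(t)
    return ts.with_traces(kept, f"vertical_trim removed {report.n_removed}"), report


# ---------------------------------------------------------------------------
# canonical direction and resampling


def canonicalize_direction(trace: FiberTrace) -> FiberTrace:
    """Orient the trace so its first point has the lower y-coordinate.

    Gives every fiber in a tomogram a common direction so local slopes
    and the fiber vector are well defined.  Ties in y are broken by
    lower x first, then lower z; the operation is idempotent.
    """
    first, last = trace.points[0], trace.points[-1]
    for axis in (1, 0, 2):  # y, then x, then z
        if last[axis] < first[axis]:
            return trace.reversed()
        if last[axis] > first[axis]:
            return trace
    return trace


def resample_cubic_spline(trace: FiberTrace, delta_nm: float = 1.0) -> FiberTrace:
    """Resample a trace at uniform arc-length spacing via cubic splines.

    Contours from tracing software have uneven point spacing; this
    reparameterizes by arc length at ~delta_nm (default 1 nm) spacing.
    Splines of order min(3, n-1) interpolate the points with chord-length
    parameterization; endpoints are preserved exactly.
    """
    pts = trace.points
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    total = t[-1]
    if total < delta_nm:
        raise ValueError(
            f"trace {trace.trace_id}: length {total:.3f} nm shorter than spacing {delta_nm} nm"
        )
    k = min(3, pts.shape[0] - 1)
    spline = make_interp_spline(t, pts, k=k)
    # dense evaluation to build the arc-length map of the *spline* curve
    n_dense = max(int(total / delta_nm) * 8, 16)
    td = np.linspace(0.0, total, n_dense + 1)
    pd = spline(td)
    sd = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pd, axis=0), axis=1))])
    length = sd[-1]
    n_int = max(1, round(length / delta_nm))
    targets = np.linspace(0.0, length, n_int + 1)
    t_new = np.interp(targets, sd, td)
    out = spline(t_new)
    out[0], out[-1] = pts[0], pts[-1]
    return FiberTrace(trace.trace_id, out)


# ---------------------------------------------------------------------------
# per-fiber statistics


def menger_radius(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Circumradius of the triangle (p1, p2, p3); inf when collinear.

    The Menger curvature of three points is 1/R of their circumscribed
    circle: R = (d12 * d23 * d13) / (4 * area).
    """
    d12 = np.linalg.norm(p2 - p1)
    d23 = np.linalg.norm(p3 - p2)
    d13 = np.linalg.norm(p3 - p1)
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    if area < DEGENERATE_TRIANGLE_AREA_NM2:
        return math.inf
    return float(d12 * d23 * d13 / (4.0 * area))


def mean_menger_radius(points: np.ndarray) -> float:
    """Mean circumradius over consecutive point triples.

    Degenerate (near-collinear) triples are excluded from the average; a
    fully collinear polyline reports inf, fewer than 3 points NaN.
    """
    n = points.shape[0]
    if n < 3:
        return math.nan
    p1, p2, p3 = points[:-2], points[1:-1], points[2:]
    a = np.linalg.norm(p2 - p1, axis=1)
    b = np.linalg.norm(p3 - p2, axis=1)
    c = np.linalg.norm(p3 - p1, axis=1)
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1), axis=1)
    ok = area >= DEGENERATE_TRIANGLE_AREA_NM2
    if not ok.any():
        return math.inf
    radii = a[ok] * b[ok] * c[ok] / (4.0 * area[ok])
    return float(radii.mean())


def polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def mean_slope(points: np.ndarray) -> float:
    """Mean of local slopes dz / dxy over consecutive point pairs.

    Pairs with zero xy displacement (locally vertical) are excluded.
    """
    d = np.diff(points, axis=0)
    dxy = np.hypot(d[:, 0], d[:, 1])
    ok = dxy > 0
    if not ok.any():
        return math.nan
    return float((d[ok, 2] / dxy[ok]).mean())


def angle_to_axis(trace: FiberTrace, cell_axis: tuple[float, float]) -> float:
    """Clockwise angle in [0, 180) between the fiber and the cell long axis.

    The fiber vector points from the lower-y end to the higher-y end
    (trace must be canonicalized).  The signed ccw angle is
    atan2(cx*fy - cy*fx, cx*fx + cy*fy); the clockwise convention maps
    it to (-angle) mod 180.  NaN if the fiber has no xy extent.
    """
    f = trace.points[-1] - trace.points[0]
    fx, fy = f[0], f[1]
    if fx == 0 and fy == 0:
        return math.nan
    cx, cy = cell_axis
    raw = math.degrees(math.atan2(cx * fy - cy * fx, cx * fx + cy * fy))
    return (-raw) % 180.0


def compute_fiber_metrics(
    trace: FiberTrace, cell_axis: tuple[float, float] = (0.0, 1.0)
) -> FiberMetrics:
    """All per-fiber statistics for one canonicalized, resampled trace."""
    pts = trace.points
    return FiberMetrics(
        trace_id=trace.trace_id,
        length_nm=polyline_length(pts),
        mean_menger_radius_nm=mean_menger_radius(pts),
        mean_slope=mean_slope(pts),
        mean_z_nm=float(pts[:, 2].mean()),
        angle_to_axis_deg=angle_to_axis(trace, cell_axis),
        n_points=pts.shape[0],
    )


def tomogram_depth(d_um: float, alpha_deg: float, mode: str = "tan") -> float:
    """Depth of a tomogram below the wall surface, in micrometres.

    Uses the nominal milling angle alpha as the inclination and the
    projected distance d from the lamella leading edge to the tomogram
    centre: depth = d * tan(alpha) when d is measured in top view
    (default), or d * sin(alpha) when d is measured along the milled
    face.
    """
    if not 0.0 <= alpha_deg < 90.0:
        raise ValueError(f"milling angle must be in [0, 90), got {alpha_deg}")
    if d_um < 0:
        raise ValueError("projected distance must be >= 0")
    a = math.radians(alpha_deg)
    if mode == "tan":
        return d_um * math.tan(a)
    if mode == "sin":
        return d_um * math.sin(a)
    raise ValueError(f"unknown depth mode {mode!r}; expected 'tan' or 'sin'")


# ---------------------------------------------------------------------------
# composed pipeline


def process_traceset(
    ts: TraceSet,
    theta_max_deg: float = 70.0,
    zz_max: float = 0.8,
    xz_abs_max: float | None = None,
    resample_delta_nm: float = 1.0,
    filter_before_rotation: bool = True,
) -> tuple[list[FiberMetrics], TraceSet, list[RejectionReport]]:
    """Run the full geometric stage chain on one tomogram's traces.

    Returns per-fiber metrics, the processed TraceSet, and the rejection
    reports of the two filter stages.  ``filter_before_rotation``
    applies the out-of-plane filter in the as-reconstructed frame
    (default) rather than after the milling-tilt correction.
    """
    alpha = ts.context.milling_angle_deg
    reports = []
    if filter_before_rotation:
        ts, rep = filter_out_of_plane(ts, theta_max_deg)
        reports.append(rep)
        ts = apply_milling_rotation(ts, alpha)
    else:
        ts = apply_milling_rotation(ts, alpha)
        ts, rep = filter_out_of_plane(ts, theta_max_deg)
        reports.append(rep)
    ts, rep = trim_vertical_artifacts(ts, zz_max=zz_max, xz_abs_max=xz_abs_max)
    reports.append(rep)
    processed = []
    for t in ts.traces:
        t = canonicalize_direction(t)
        try:
            t = resample_cubic_spline(t, resample_delta_nm)
        except ValueError:
            pass  # shorter than one sampling step: keep original points
        processed.append(t)
    ts = ts.with_traces(processed, f"resampled at {resample_delta_nm} nm")
    metrics = [compute_fiber_metrics(t, ts.context.cell_axis) for t in ts.traces]
    return metrics, ts, reports


def metrics_to_dataframe(metrics: list[FiberMetrics], context=None):
    """Tabulate per-fiber metrics, attaching context labels when given."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "trace_id": m.trace_id,
                "length_nm": m.length_nm,
                "menger_radius_nm": m.mean_menger_radius_nm,
                "slope": m.mean_slope,
                "mean_z_nm": m.mean_z_nm,
                "angle_deg": m.angle_to_axis_deg,
                "n_points": m.n_points,
            }
            for m in metrics
        ]
    )
    if context is not None:
        df["depth_um"] = context.depth_um
        df["scale"] = context.scale_number
        df["treatment"] = context.treatment
    return df
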