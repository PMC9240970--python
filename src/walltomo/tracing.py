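"""Template-matching fiber tracing on probability maps.

A functional analog of cylinder-correlation tracing: every voxel is
scored by normalized cross-correlation against a soft cylinder
template over a grid of orientations, then lines are traced greedily
from high-correlation seeds by stepping inside a search cone, blending
the current heading with the local best-match orientation.  Parameter
names and defaults mirror the published tracing configuration
(cylinder length 50 px, angular sampling 5 deg, mask radius 125% of
the outer cylinder radius, minimal line length 60 px, direction
coefficient 0.3, cone 37 deg / 80 px look-ahead / 10% minimal step,
minimal line distance twice the cylinder diameter); the stepping and
blending internals are original.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter
from scipy.signal import fftconvolve

from .datatypes import DensityVolume, FiberTrace, TomogramContext, TraceSet

_FWHM_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class TracingParams:
    """Tracing configuration; lengths/radii in voxels (px)."""

    cylinder_length_px: float = 50.0
    outer_radius_px: float = 4.0
    mask_radius_factor: float = 1.25
    angular_step_deg: float = 5.0
    min_seed_corr: float = 0.5
    min_cont_corr: float = 0.3
    min_line_length_px: float = 60.0
    direction_coefficient: float = 0.3
    search_cone_deg: float = 37.0
    search_cone_length_px: float = 80.0
    min_step_fraction: float = 0.10
    min_line_distance_px: float | None = None  # default: 2 x cylinder diameter
    out_of_plane_deg: tuple[float, ...] = (0.0,)
    max_steps: int = 10000

    def __post_init__(self) -> None:
        if not (0.0 < self.search_cone_deg < 90.0):
            raise ValueError("search_cone_deg must be in (0, 90)")
        if self.min_seed_corr < self.min_cont_corr:
            raise ValueError("min_seed_corr must be >= min_cont_corr")
        if self.min_line_distance_px is None:
            object.__setattr__(self, "min_line_distance_px", 4.0 * self.outer_radius_px)

    @property
    def step_px(self) -> float:
        return max(self.min_step_fraction * self.search_cone_length_px, 1.0)


def orientation_grid(params: TracingParams) -> np.ndarray:
    """Unit direction vectors (x, y, z) of the orientation search grid.

    In-plane axial angles sweep [0, 180) at the angular step; each is
    combined with every configured out-of-plane inclination.
    """
    thetas = np.arange(0.0, 180.0, params.angular_step_deg)
    dirs = []
    for psi_deg in params.out_of_plane_deg:
        psi = math.radians(psi_deg)
        for th_deg in thetas:
            th = math.radians(th_deg)
            dirs.append(
                (math.sin(th) * math.cos(psi), math.cos(th) * math.cos(psi), math.sin(psi))
            )
    return np.asarray(dirs)


def _cylinder_template(direction: np.ndarray, params: TracingParams):
    """Soft cylinder template and its mask on a minimal cube grid.

    The template has a Gaussian cross-section whose half-maximum radius
    equals outer_radius_px; the correlation mask is a cylinder of
    radius mask_radius_factor x outer_radius_px.
    """
    L = params.cylinder_length_px
    rmask = params.mask_radius_factor * params.outer_radius_px
    half_ax = L / 2.0
    # bounding half-extent per axis from the oriented cylinder
    d = np.abs(direction)
    half = np.ceil(half_ax * d + rmask * np.sqrt(np.maximum(1.0 - d**2, 0.0)) + 1).astype(int)
    xs = np.arange(-half[0], half[0] + 1)
    ys = np.arange(-half[1], half[1] + 1)
    zs = np.arange(-half[2], half[2] + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pos = np.stack([X, Y, Z], axis=-1).astype(float)
    axial = pos @ direction
    perp2 = (pos**2).sum(axis=-1) - axial**2
    mask = (np.abs(axial) <= half_ax) & (perp2 <= rmask**2)
    sigma = params.outer_radius_px * _FWHM_SIGMA
    tube = np.exp(-perp2 / (2.0 * sigma**2)) * mask
    nm = mask.sum()
    t0 = np.where(mask, tube - tube[mask].mean(), 0.0)
    tnorm = math.sqrt(float((t0[mask] ** 2).sum()))
    return t0, mask.astype(float), nm, tnorm


def cylinder_correlation(
    vol: DensityVolume, params: TracingParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized cross-correlation against oriented cylinder templates.

    Returns (corr_field, orient_index_field, orientations): the
    per-voxel maximum NCC in [-1, 1] over the orientation grid, the
    argmax orientation index, and the grid's direction vectors.  Voxels
    whose local masked variance vanishes (flat signal) are NaN.
    """
    f = np.asarray(vol.data, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("volume contains non-finite voxels")
    dirs = orientation_grid(params)
    if f.size and f.max() == f.min():
        # globally flat signal: correlation undefined everywhere
        return (
            np.full(f.shape, np.nan, dtype=np.float32),
            np.zeros(f.shape, dtype=np.int32),
            dirs,
        )
    best = np.full(f.shape, -np.inf)
    argbest = np.zeros(f.shape, dtype=np.int32)
    f2 = f * f
    any_valid = np.zeros(f.shape, dtype=bool)
    for k, direction in enumerate(dirs):
        t0, mask, nm, tnorm = _cylinder_template(direction, params)
        if any(ts > fs for ts, fs in zip(t0.shape, f.shape)):
            raise ValueError(
                f"template {t0.shape} larger than volume {f.shape}; "
                "reduce cylinder_length_px"
            )
        flip = (slice(None, None, -1),) * 3
        num = fftconvolve(f, t0[flip], mode="same")
        s1 = fftconvolve(f, mask[flip], mode="same")
        s2 = fftconvolve(f2, mask[flip], mode="same")
        var = np.maximum(s2 - s1 * s1 / nm, 0.0)
        denom = np.sqrt(var) * tnorm
        # flat local patches (variance at numerical-noise level relative to
        # the local mean square) and patches with negligible energy relative
        # to the global signal are undefined, not zero-correlated
        valid = (var > 1e-6 * np.maximum(s2, 1e-30)) & (
            s2 > 1e-9 * nm * f2.max()
        )
        corr = np.full(f.shape, -np.inf)
        np.divide(num, denom, out=corr, where=valid)
        np.clip(corr, -1.0, 1.0, out=corr)
        better = corr > best
        best[better] = corr[better]
        argbest[better] = k
        any_valid |= valid
    best[~any_valid] = np.nan
    return best.astype(np.float32), argbest, dirs


def _kdtree(points: list[np.ndarray]):
    from scipy.spatial import cKDTree

    if not points:
        return None
    return cKDTree(np.concatenate(points, axis=0))


def _in_bounds(p: np.ndarray, shape) -> bool:
    nz, ny, nx = shape
    return 0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1 and 0 <= p[2] <= nz - 1


def _corr_at(corr: np.ndarray, p: np.ndarray) -> float:
    val = map_coordinates(
        corr, np.array([[p[2]], [p[1]], [p[0]]]), order=1, mode="constant", cval=-1.0
    )
    return float(val[0])


def _orient_at(orient: np.ndarray, dirs: np.ndarray, p: np.ndarray) -> np.ndarray:
    idx = orient[
        int(round(p[2])).__index__(), int(round(p[1])), int(round(p[0]))
    ]
    return dirs[idx]


def trace_correlation_lines(
    corr: np.ndarray,
    orient_index: np.ndarray,
    orientations: np.ndarray,
    params: TracingParams,
    voxel_size_nm: float = 1.0,
    context: TomogramContext | None = None,
) -> TraceSet:
    """Greedy bidirectional line tracing on a correlation field.

    Seeds are local correlation maxima above min_seed_corr, visited in
    descending correlation (ties broken by voxel index).  From each
    seed the line steps toward the best-correlated direction inside a
    cone of half-angle search_cone_deg around the current heading; the
    heading is then blended with the local template orientation by the
    direction coefficient.  Extension stops when the best correlation
    falls below min_cont_corr, the cone leaves the volume, or the line
    would pass within min_line_distance_px of an accepted trace.
    """
    shape = corr.shape
    cwork = np.where(np.isnan(corr), -1.0, corr)
    local_max = cwork == maximum_filter(cwork, size=3, mode="constant", cval=-1.0)
    seed_mask = local_max & (cwork >= params.min_seed_corr)
    zz, yy, xx = np.nonzero(seed_mask)
    if zz.size == 0:
        return TraceSet([], context or TomogramContext(voxel_size_nm=voxel_size_nm))
    vals = cwork[zz, yy, xx]
    order = np.lexsort((xx, yy, zz, -vals))  # corr desc, then lexicographic
    seeds = np.column_stack([xx, yy, zz])[order]

    step = params.step_px
    cone = math.radians(params.search_cone_deg)
    n_cand = max(3, int(round(2 * params.search_cone_deg / params.angular_step_deg)) + 1)
    deltas = np.linspace(-cone, cone, n_cand)

    accepted_points: list[np.ndarray] = []
    traces: list[FiberTrace] = []
    tid = 0

    def too_close(p: np.ndarray, tree) -> bool:
        if tree is None:
            return False
        return bool(tree.query(p, k=1)[0] < params.min_line_distance_px)

    def extend(start: np.ndarray, heading: np.ndarray, tree) -> list[np.ndarray]:
        pts = []
        p = start.astype(float).copy()
        h = heading / np.linalg.norm(heading)
        for _ in range(params.max_steps):
            # candidate directions: in-plane rotations of the heading
            phi = math.atan2(h[0], h[1])
            hz = h[2]
            hxy = math.hypot(h[0], h[1])
            best_c, best_dir, best_p = -np.inf, None, None
            for dlt in deltas:
                a = phi + dlt
                cand = np.array([hxy * math.sin(a), hxy * math.cos(a), hz])
                cand /= np.linalg.norm(cand)
                q = p + step * cand
                if not _in_bounds(q, shape):
                    continue
                c = _corr_at(cwork, q)
                if c > best_c:
                    best_c, best_dir, best_p = c, cand, q
            if best_dir is None or best_c < params.min_cont_corr:
                break
            if too_close(best_p, tree):
                break
            o = _orient_at(orient_index, orientations, best_p)
            if float(o @ best_dir) < 0:
                o = -o
            h = (1.0 - params.direction_coefficient) * best_dir + (
                params.direction_coefficient * o
            )
            h /= np.linalg.norm(h)
            p = best_p
            pts.append(p.copy())
        return pts

    for seed in seeds:
        tree = _kdtree(accepted_points)
        pseed = seed.astype(float)
        if too_close(pseed, tree):
            continue
        if cwork[seed[2], seed[1], seed[0]] < params.min_seed_corr:
            continue
        h0 = orientations[orient_index[seed[2], seed[1], seed[0]]]
        fwd = extend(pseed, h0, tree)
        bwd = extend(pseed, -h0, tree)
        pts = bwd[::-1] + [pseed] + fwd
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        length = float(np.linalg.norm(np.diff(arr, axis=0), axis=1).sum())
        if length < params.min_line_length_px:
            continue
        accepted_points.append(arr)
        traces.append(FiberTrace(tid, arr * voxel_size_nm))
        tid += 1

    ctx = context or TomogramContext(voxel_size_nm=voxel_size_nm)
    return TraceSet(traces, ctx, provenance=f"traced {len(traces)} lines")


def trace_volume(
    vol: DensityVolume, params: TracingParams, context: TomogramContext | None = None
) -> TraceSet:
    """cylinder_correlation + trace_correlation_lines in one call; nm output."""
    corr, orient, dirs = cylinder_correlation(vol, params)
    return trace_correlation_lines(
        corr, orient, dirs, params, voxel_size_nm=vol.voxel_size_nm, context=context
    )
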