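"""Ground-truthed synthetic cell-wall phantoms.

Generates layered fiber fields whose in-plane orientations follow an
axial (180-degree periodic) von Mises law around one or two configured
modes, an isotropic reticulated "meshing" network whose abundance
decays exponentially with depth, and soft-tube probability volumes
emulating CNN segmentation maps (a fiber-only map and an all-features
map).  Every generated object carries a ground-truth table so each
downstream stage can be validated against configured truth.

Coordinate convention: x, y, z in nm; z = 0 is the wall surface and
depth increases with z.  The reference axis for fiber angles is +y
(cell long axis (0, 1)), so a fiber with angle theta runs along
(sin theta, cos theta) in the xy-plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import DensityVolume, FiberTrace, TomogramContext, TraceSet

PATTERNS = ("staggered", "overlapped", "staggered_overlapped", "unimodal")

# Gaussian tube cross-sections are parameterized so the half-maximum
# radius equals the nominal tube radius: sigma = r / sqrt(2 ln 2).
_FWHM_SIGMA = 1.0 / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class FiberFieldSpec:
    """Configuration of a layered bimodal fiber field.

    mode_angles are axial angles in degrees relative to the +y reference
    axis; angular_sd is the per-fiber angular spread around its mode.
    The four stacking patterns control how the orientation modes occupy
    z: ``staggered`` alternates single-mode layers, ``overlapped`` mixes
    both modes at all heights, ``staggered_overlapped`` keeps alternating
    layers but lets fibers spill across layer boundaries, ``unimodal``
    uses a single mode everywhere.
    """

    box_dims: tuple[float, float, float] = (1000.0, 1000.0, 400.0)
    n_layers: int = 8
    layer_thickness: float = 50.0
    mode_angles: tuple[float, ...] = (45.0, 135.0)
    angular_sd: float = 8.0
    pattern: str = "staggered"
    fiber_spacing: float = 40.0
    fiber_length_range: tuple[float, float] = (300.0, 600.0)
    curvature_radius: float = math.inf
    slope_sd: float = 0.02
    fibers_per_layer: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if any(d <= 0 for d in self.box_dims):
            raise ValueError("box_dims must be positive")
        if self.angular_sd < 0:
            raise ValueError("angular_sd must be >= 0")
        if not all(0.0 <= m < 180.0 for m in self.mode_angles):
            raise ValueError("mode_angles must lie in [0, 180)")
        if self.pattern == "unimodal" and len(self.mode_angles) != 1:
            object.__setattr__(self, "mode_angles", (self.mode_angles[0],))
        if self.n_layers * self.layer_thickness > self.box_dims[2] + 1e-9:
            raise ValueError("layer stack exceeds box z-extent")
        lo, hi = self.fiber_length_range
        if not (0 < lo <= hi):
            raise ValueError("fiber_length_range must be positive and ordered")
        if hi > min(self.box_dims[0], self.box_dims[1]):
            raise ValueError(
                f"box too small for fiber_length_range: max length {hi} nm exceeds "
                f"min lateral extent {min(self.box_dims[0], self.box_dims[1])} nm"
            )


@dataclass(frozen=True)
class MeshingSpec:
    """Configuration of the reticulated meshing network.

    density_at_surface is in segments per cubic micrometre at depth 0;
    abundance decays as exp(-depth / depth_decay).  The morphology
    parameters (segment lengths, branching) are free parameters of the
    generator: no quantitative meshing morphology is available to
    emulate, only the depth trend.
    """

    segment_length_range: tuple[float, float] = (20.0, 60.0)
    branch_probability: float = 0.15
    density_at_surface: float = 400.0
    depth_decay: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ValueError("branch_probability must be in [0, 1]")
        if self.density_at_surface < 0:
            raise ValueError("density_at_surface must be >= 0")
        if self.depth_decay <= 0:
            raise ValueError("depth_decay must be positive (use math.inf for no decay)")


@dataclass(frozen=True)
class RenderSpec:
    """Voxelization parameters for probability-map rendering."""

    voxel_size: float = 2.0
    fiber_radius: float = 3.5
    meshing_radius: float = 1.75
    psf_sigma: float = 0.0
    noise_sd: float = 0.0
    memory_budget_mb: float = 1024.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.fiber_radius <= 0:
            raise ValueError("voxel_size and fiber_radius must be positive")


@dataclass
class MeshingGraph:
    """Node/edge representation of the meshing network, coordinates in nm."""

    nodes: np.ndarray  # (n, 3)
    edges: np.ndarray  # (m, 2) int indices into nodes

    @property
    def n_segments(self) -> int:
        return int(self.edges.shape[0])

    def segment_midpoints(self) -> np.ndarray:
        if self.n_segments == 0:
            return np.empty((0, 3))
        return 0.5 * (self.nodes[self.edges[:, 0]] + self.nodes[self.edges[:, 1]])

    def segment_lengths(self) -> np.ndarray:
        if self.n_segments == 0:
            return np.empty(0)
        return np.linalg.norm(
            self.nodes[self.edges[:, 1]] - self.nodes[self.edges[:, 0]], axis=1
        )


# ---------------------------------------------------------------------------
# fiber field


def _sample_axial_angle(rng, mode_deg: float, sd_deg: float) -> float:
    """Draw an axial angle: von Mises noise on the doubled circle."""
    if sd_deg == 0:
        return mode_deg % 180.0
    kappa = 1.0 / (2.0 * math.radians(sd_deg)) ** 2
    phi = rng.vonmises(0.0, kappa)  # doubled-angle deviation
    return (mode_deg + math.degrees(phi) / 2.0) % 180.0


def _fiber_polyline(
    center: np.ndarray,
    theta_deg: float,
    length: float,
    slope: float,
    radius: float,
    bend_sign: float,
    max_spacing: float = 2.0,
) -> np.ndarray:
    """Sample one fiber as a constant-curvature arc (or chord) polyline.

    The arc lies in a plane through ``center`` spanned by the in-plane
    direction (sin t, cos t) and its normal; z rises linearly with
    in-plane arc length at the given slope.  The chord of a symmetric
    arc is parallel to the direction vector, so the end-to-end in-plane
    angle equals theta exactly.
    """
    th = math.radians(theta_deg)
    d = np.array([math.sin(th), math.cos(th), 0.0])
    nvec = np.array([math.cos(th), -math.sin(th), 0.0])
    n_seg = max(2, int(math.ceil(length * math.hypot(1.0, slope) / max_spacing)))
    s = np.linspace(-length / 2.0, length / 2.0, n_seg + 1)
    if math.isinf(radius):
        xy = center[None, :] + s[:, None] * d[None, :]
    else:
        ang = s / radius
        xy = (
            center[None, :]
            + radius * np.sin(ang)[:, None] * d[None, :]
            + bend_sign * radius * (1.0 - np.cos(ang))[:, None] * nvec[None, :]
        )
    pts = xy.copy()
    pts[:, 2] += slope * s  # dz/d(xy arc length) = slope
    return pts


def generate_fiber_field(spec: FiberFieldSpec) -> tuple[TraceSet, pd.DataFrame]:
    """Generate a layered fiber field with per-fiber ground truth.

    Returns a TraceSet (polylines sampled at <= 2 nm spacing) and a
    truth table with one row per fiber: configured mode, drawn angle,
    layer index, length, slope and z placement.
    """
    rng = np.random.default_rng(spec.seed)
    bx, by, bz = spec.box_dims
    stack_z = spec.n_layers * spec.layer_thickness
    n_modes = len(spec.mode_angles)
    if spec.fibers_per_layer is not None:
        n_per_layer = spec.fibers_per_layer
    else:
        n_per_layer = max(1, round(math.hypot(bx, by) / spec.fiber_spacing))

    traces: list[FiberTrace] = []
    rows = []
    fid = 0
    for layer in range(spec.n_layers):
        z_lo = layer * spec.layer_thickness
        z_hi = z_lo + spec.layer_thickness
        for _ in range(n_per_layer):
            if spec.pattern == "unimodal":
                mode_idx = 0
            elif spec.pattern == "overlapped":
                mode_idx = int(rng.integers(n_modes))
            else:  # staggered, staggered_overlapped
                mode_idx = layer % n_modes
            theta = _sample_axial_angle(rng, spec.mode_angles[mode_idx], spec.angular_sd)
            length = float(rng.uniform(*spec.fiber_length_range))
            slope = float(rng.normal(0.0, spec.slope_sd)) if spec.slope_sd > 0 else 0.0
            if spec.pattern in ("overlapped", "unimodal"):
                zc = float(rng.uniform(0.0, stack_z))
            elif spec.pattern == "staggered":
                zc = float(rng.uniform(z_lo, z_hi))
            else:  # staggered_overlapped: spill halfway into neighbours
                half = 0.5 * spec.layer_thickness
                zc = float(
                    np.clip(rng.uniform(z_lo - half, z_hi + half), 0.0, stack_z)
                )
            cx = float(rng.uniform(length / 2.0, bx - length / 2.0))
            cy = float(rng.uniform(length / 2.0, by - length / 2.0))
            bend = float(rng.choice([-1.0, 1.0]))
            pts = _fiber_polyline(
                np.array([cx, cy, zc]),
                theta,
                length,
                slope,
                spec.curvature_radius,
                bend,
            )
            traces.append(FiberTrace(fid, pts))
            rows.append(
                {
                    "fiber_id": fid,
                    "mode_index": mode_idx,
                    "mode_angle_deg": spec.mode_angles[mode_idx],
                    "true_angle_deg": theta,
                    "layer_index": layer,
                    "length_nm": length,
                    "slope": slope,
                    "z_center_nm": zc,
                }
            )
            fid += 1
    ctx = TomogramContext(voxel_size_nm=1.0, cell_axis=(0.0, 1.0))
    ts = TraceSet(traces, context=ctx, provenance=f"synthetic fiber field seed={spec.seed}")
    return ts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meshing network


def generate_meshing_network(spec: MeshingSpec, box_dims) -> MeshingGraph:
    """Generate an isotropic branched segment network with depth decay.

    Segment midpoint depth follows a truncated-exponential law with
    characteristic depth ``depth_decay``; orientations are uniform on
    the sphere.  Each primary segment spawns a branch with probability
    ``branch_probability`` from a random point along its run.
    """
    rng = np.random.default_rng(spec.seed)
    bx, by, bz = box_dims
    area_um2 = (bx / 1000.0) * (by / 1000.0)
    if math.isinf(spec.depth_decay):
        eff_depth_um = bz / 1000.0
    else:
        lam = spec.depth_decay / 1000.0
        eff_depth_um = lam * (1.0 - math.exp(-(bz / 1000.0) / lam))
    expected = spec.density_at_surface * area_um2 * eff_depth_um
    n = int(rng.poisson(expected)) if expected > 0 else 0
    if n == 0:
        return MeshingGraph(np.empty((0, 3)), np.empty((0, 2), dtype=int))

    # midpoint depth via inverse CDF of the truncated exponential
    u = rng.uniform(size=n)
    if math.isinf(spec.depth_decay):
        z = u * bz
    else:
        lam = spec.depth_decay
        z = -lam * np.log1p(-u * (1.0 - math.exp(-bz / lam)))
    mid = np.column_stack([rng.uniform(0, bx, n), rng.uniform(0, by, n), z])

    def _isotropic_dirs(k):
        v = rng.normal(size=(k, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    dirs = _isotropic_dirs(n)
    lengths = rng.uniform(*spec.segment_length_range, size=n)
    a = mid - 0.5 * lengths[:, None] * dirs
    b = mid + 0.5 * lengths[:, None] * dirs

    nodes = [a, b]
    edges = [np.column_stack([np.arange(n), np.arange(n) + n])]
    next_idx = 2 * n
    branch = rng.uniform(size=n) < spec.branch_probability
    if branch.any():
        k = int(branch.sum())
        t = rng.uniform(size=k)
        start = a[branch] + t[:, None] * (b[branch] - a[branch])
        bdirs = _isotropic_dirs(k)
        blen = rng.uniform(*spec.segment_length_range, size=k)
        end = start + blen[:, None] * bdirs
        nodes.extend([start, end])
        edges.append(
            np.column_stack([next_idx + np.arange(k), next_idx + k + np.arange(k)])
        )
    all_nodes = np.concatenate(nodes, axis=0)
    all_edges = np.concatenate(edges, axis=0).astype(int)
    return MeshingGraph(all_nodes, all_edges)


# ---------------------------------------------------------------------------
# rendering


def _deposit_polyline(grid: np.ndarray, pts_vox: np.ndarray, step_vox: float) -> None:
    """Accumulate unit deposits along a polyline onto the voxel grid."""
    seg = np.diff(pts_vox, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    samples = [pts_vox[0]]
    for i, L in enumerate(seg_len):
        if L == 0:
            continue
        k = max(1, int(math.ceil(L / step_vox)))
        t = (np.arange(k) + 1.0) / k
        samples.append(pts_vox[i] + t[:, None] * seg[i])
    pv = np.concatenate([np.atleast_2d(s) for s in samples], axis=0)
    ijk = np.round(pv).astype(int)  # (x, y, z) voxel indices
    nz, ny, nx = grid.shape
    ok = (
        (ijk[:, 0] >= 0) & (ijk[:, 0] < nx)
        & (ijk[:, 1] >= 0) & (ijk[:, 1] < ny)
        & (ijk[:, 2] >= 0) & (ijk[:, 2] < nz)
    )
    ijk = ijk[ok]
    np.add.at(grid, (ijk[:, 2], ijk[:, 1], ijk[:, 0]), 1.0)


def _soft_tube_map(
    polylines: list[np.ndarray], shape, voxel: float, radius_nm: float, psf_nm: float
) -> np.ndarray:
    """Render polylines as soft tubes with Gaussian cross-section.

    Intensity at a voxel is exp(-d^2 / 2 sigma^2) of its distance d to
    the nearest centreline, with sigma set so the half-maximum radius
    equals ``radius_nm`` (axis intensity exactly 1).  An optional
    Gaussian PSF blur is applied on top.
    """
    from scipy.ndimage import distance_transform_edt

    skel = np.zeros(shape, dtype=np.float64)
    for pts in polylines:
        _deposit_polyline(skel, pts / voxel, 0.25)
    if not skel.any():
        return np.zeros(shape)
    dist_nm = distance_transform_edt(skel == 0) * voxel
    sigma = radius_nm * _FWHM_SIGMA
    out = np.exp(-(dist_nm**2) / (2.0 * sigma**2))
    if psf_nm > 0:
        out = gaussian_filter(out, sigma=psf_nm / voxel, mode="constant")
    return out


def render_probability_maps(
    traces: TraceSet | list[np.ndarray],
    meshing: MeshingGraph | None,
    render: RenderSpec,
    box_dims,
) -> tuple[DensityVolume, DensityVolume]:
    """Render fiber-only and all-features probability volumes.

    Emulates CNN segmentation output: soft tubes of Gaussian
    cross-section around fiber polylines (fiber map) plus meshing
    segments (all-features map), clipped to [0, 1], with white Gaussian
    noise added last.
    """
    bx, by, bz = box_dims
    v = render.voxel_size
    shape = (max(1, round(bz / v)), max(1, round(by / v)), max(1, round(bx / v)))
    n_vox = shape[0] * shape[1] * shape[2]
    need_mb = n_vox * 8 * 3 / 1e6
    if need_mb > render.memory_budget_mb:
        raise MemoryError(
            f"render grid {shape} needs ~{need_mb:.0f} MB, exceeds budget "
            f"{render.memory_budget_mb:.0f} MB"
        )
    polylines = [t.points for t in traces] if isinstance(traces, TraceSet) else list(traces)
    fiber = _soft_tube_map(polylines, shape, v, render.fiber_radius, render.psf_sigma)
    if meshing is not None and meshing.n_segments > 0:
        mesh_lines = [
            np.stack([meshing.nodes[i], meshing.nodes[j]]) for i, j in meshing.edges
        ]
        mesh = _soft_tube_map(mesh_lines, shape, v, render.meshing_radius, render.psf_sigma)
    else:
        mesh = np.zeros(shape)
    fiber = np.clip(fiber, 0.0, 1.0)
    allf = np.clip(np.maximum(fiber, mesh), 0.0, 1.0)
    if render.noise_sd > 0:
        rng = np.random.default_rng(render.seed)
        fiber = fiber + rng.normal(0.0, render.noise_sd, shape)
        allf = allf + rng.normal(0.0, render.noise_sd, shape)
    return (
        DensityVolume(fiber.astype(np.float32), voxel_size_nm=v),
        DensityVolume(allf.astype(np.float32), voxel_size_nm=v),
    )


# ---------------------------------------------------------------------------
# phantom bundles


@dataclass
class Phantom:
    """A fully rendered synthetic tomogram with ground truth."""

    traces: TraceSet
    truth: pd.DataFrame
    meshing: MeshingGraph
    fiber_map: DensityVolume
    all_features_map: DensityVolume
    field_spec: FiberFieldSpec
    meshing_spec: MeshingSpec
    render_spec: RenderSpec

    def ground_truth_tube_volumes(self) -> tuple[float, float]:
        """Analytic (fiber, meshing) tube volumes in nm^3 at nominal radii."""
        fib_len = sum(
            float(np.linalg.norm(np.diff(t.points, axis=0), axis=1).sum())
            for t in self.traces
        )
        mesh_len = float(self.meshing.segment_lengths().sum())
        rf = self.render_spec.fiber_radius
        rm = self.render_spec.meshing_radius
        return math.pi * rf**2 * fib_len, math.pi * rm**2 * mesh_len

    def ground_truth_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxelized true tube masks (fiber, meshing) on the render grid.

        A voxel belongs to a tube when its centre lies within the
        nominal tube radius of the centreline (distance-transform
        voxelization).  Meshing voxels also covered by fiber are
        excluded, mirroring the subtraction step, so the voxel-count
        ratio of these masks is the ground-truth occupancy ratio the
        pipeline should recover.
        """
        from scipy.ndimage import distance_transform_edt

        from .synthetic import _deposit_polyline  # self-import for clarity

        shape = self.fiber_map.shape
        v = self.render_spec.voxel_size

        def tube_mask(lines, radius_nm):
            skel = np.zeros(shape)
            for pts in lines:
                _deposit_polyline(skel, pts / v, 0.25)
            dist = distance_transform_edt(skel == 0)
            return dist <= radius_nm / v

        fib = tube_mask([t.points for t in self.traces], self.render_spec.fiber_radius)
        mesh_lines = [
            np.stack([self.meshing.nodes[i], self.meshing.nodes[j]])
            for i, j in self.meshing.edges
        ]
        mesh = tube_mask(mesh_lines, self.render_spec.meshing_radius)
        mesh &= ~fib
        return fib, mesh


def make_phantom(
    field_spec: FiberFieldSpec,
    meshing_spec: MeshingSpec | None = None,
    render_spec: RenderSpec | None = None,
) -> Phantom:
    """Generate fibers + meshing and render both probability maps."""
    meshing_spec = meshing_spec or MeshingSpec(seed=field_spec.seed + 1)
    render_spec = render_spec or RenderSpec(seed=field_spec.seed + 2)
    ts, truth = generate_fiber_field(field_spec)
    mesh = generate_meshing_network(meshing_spec, field_spec.box_dims)
    fiber_map, all_map = render_probability_maps(
        ts, mesh, render_spec, field_spec.box_dims
    )
    return Phantom(ts, truth, mesh, fiber_map, all_map, field_spec, meshing_spec, render_spec)


def write_phantom(phantom: Phantom, outdir: str | Path) -> dict[str, str]:
    """Write maps, traces, truth table and specs; returns path map."""
    from . import io as wio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fiber_map": str(outdir / "fiber_map.mrc"),
        "all_features_map": str(outdir / "all_features_map.mrc"),
        "traces": str(outdir / "traces.csv"),
        "truth": str(outdir / "truth.csv"),
        "spec": str(outdir / "phantom_spec.json"),
    }
    wio.write_volume(phantom.fiber_map, paths["fiber_map"])
    wio.write_volume(phantom.all_features_map, paths["all_features_map"])
    wio.write_trace_table(phantom.traces, paths["traces"], dialect="xyz_csv")
    phantom.truth.to_csv(paths["truth"], index=False)
    spec_doc = {
        "field": asdict(phantom.field_spec),
        "meshing": asdict(phantom.meshing_spec),
        "render": asdict(phantom.render_spec),
    }
    Path(paths["spec"]).write_text(json.dumps(spec_doc, indent=2, default=float))
    return paths
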