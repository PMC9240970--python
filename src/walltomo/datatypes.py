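"""Core in-memory containers shared across the pipeline.

All coordinates are stored in nanometres; unit conversion happens only at
I/O boundaries.  Volumes are indexed ``[z, y, x]`` with 0-based voxel
indices, and a point's physical position is its voxel index times the
voxel size (voxel-centre convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

TREATMENTS = ("none", "BAPTA", "PL")


@dataclass(frozen=True)
class FiberTrace:
    """One traced fiber contour: an ordered 3D polyline in nm."""

    trace_id: int
    points: np.ndarray  # (n, 3) float array, columns x, y, z in nm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"trace {self.trace_id}: points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError(f"trace {self.trace_id}: needs >= 2 points")
        if not np.isfinite(pts).all():
            raise ValueError(f"trace {self.trace_id}: non-finite coordinates")
        if (np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0).any():
            raise ValueError(f"trace {self.trace_id}: consecutive duplicate points")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def reversed(self) -> "FiberTrace":
        return FiberTrace(self.trace_id, self.points[::-1].copy())


@dataclass(frozen=True)
class TomogramContext:
    """Per-tomogram acquisition geometry and metadata.

    milling_angle_deg is the nominal FIB milling inclination alpha;
    cell_axis is the unit vector of the cell's long axis in the tomogram
    xy frame; projected_distance_um is the top-view distance d from the
    tomogram centre to the lamella leading edge, from which the depth in
    the wall is derived.
    """

    milling_angle_deg: float = 0.0
    voxel_size_nm: float = 1.0
    cell_axis: tuple[float, float] = (0.0, 1.0)
    projected_distance_um: float = 0.0
    scale_number: int = 0
    treatment: str = "none"
    depth_um: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.milling_angle_deg < 90.0):
            raise ValueError(f"milling angle must be in [0, 90), got {self.milling_angle_deg}")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        if self.projected_distance_um < 0:
            raise ValueError("projected distance must be >= 0")
        norm = math.hypot(*self.cell_axis)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("cell_axis must be non-zero")
            object.__setattr__(
                self, "cell_axis", (self.cell_axis[0] / norm, self.cell_axis[1] / norm)
            )
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")


@dataclass
class TraceSet:
    """A collection of fiber traces from one tomogram."""

    traces: list[FiberTrace]
    context: TomogramContext = field(default_factory=TomogramContext)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.trace_id for t in self.traces]
        if len(ids) != len(set(ids)):
            raise ValueError("trace_ids must be unique within a TraceSet")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[FiberTrace]:
        return iter(self.traces)

    def with_traces(self, traces: Sequence[FiberTrace], note: str = "") -> "TraceSet":
        prov = self.provenance if not note else (self.provenance + "; " + note).lstrip("; ")
        return TraceSet(list(traces), self.context, prov)


@dataclass(frozen=True)
class FiberMetrics:
    """Per-fiber derived statistics.

    mean_menger_radius_nm is math.inf for a perfectly straight (collinear)
    fiber and NaN when fewer than 3 points are available.
    angle_to_axis_deg is the clockwise angle to the cell long axis in
    [0, 180), NaN when the xy projection of the fiber vector vanishes.
    """

    trace_id: int
    length_nm: float
    mean_menger_radius_nm: float
    mean_slope: float
    mean_z_nm: float
    angle_to_axis_deg: float
    n_points: int


@dataclass
class DensityVolume:
    """A 3D probability/density voxel grid, data indexed [z, y, x]."""

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_nm3(self) -> float:
        return float(self.voxel_size_nm**3)


@dataclass
class BinaryMask:
    """Boolean twin of a DensityVolume."""

    grid: np.ndarray
    voxel_size_nm: float
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def count(self) -> int:
        return int(self.grid.sum())

    @property
    def volume_nm3(self) -> float:
        return self.count * float(self.voxel_size_nm**3)


def traces_as_arrays(traces: Sequence[FiberTrace]) -> list[np.ndarray]:
    return [t.points for t in traces]


def map_points(ts: TraceSet, fn) -> TraceSet:
    """Apply ``fn: (n,3) -> (n,3)`` to every trace's points."""
    new = [FiberTrace(t.trace_id, fn(t.points)) for t in ts.traces]
    return replace_traces(ts, new)


def replace_traces(ts: TraceSet, traces: Sequence[FiberTrace]) -> TraceSet:
    return TraceSet(list(traces), ts.context, ts.provenance)
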