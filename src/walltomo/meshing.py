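"""Meshing segmentation by map subtraction and voxel occupancy.

A fiber-trained probability map is thresholded into a fiber mask; the
mask is subtracted from the all-features map, and what remains above a
second threshold is the meshing (everything that is not fiber is
assumed to be meshing).  Volume occupancy is measured as voxel count
times voxel volume; this replaces the contour-cylinder volume of the
original tooling, which shifts absolute ratios but not trends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .datatypes import BinaryMask, DensityVolume, TomogramContext


def binarize_map(
    vol: DensityVolume, threshold: float, strict: bool = False
) -> BinaryMask:
    """Threshold a density map into a boolean mask.

    A voxel is kept when its value is >= threshold (or > threshold when
    ``strict``).  Threshold choice is deliberate, explicit config: the
    appropriate level depends on how the upstream segmentation map was
    produced and is a judgment this pipeline does not automate.
    """
    data = vol.data
    if not np.isfinite(data).all():
        raise ValueError("volume contains non-finite voxels")
    grid = (data > threshold) if strict else (data >= threshold)
    return BinaryMask(grid, vol.voxel_size_nm, vol.origin_nm)


def subtract_fiber_mask(
    all_features: DensityVolume,
    fiber_mask: BinaryMask,
    meshing_threshold: float,
    dilate_radius_vox: int = 0,
    strict: bool = False,
) -> BinaryMask:
    """Isolate the meshing: zero out fiber voxels, threshold the rest.

    Voxels under the (optionally dilated) fiber mask are excluded, so
    the result is disjoint from the fiber mask by construction.
    """
    if all_features.data.shape != fiber_mask.grid.shape:
        raise ValueError(
            f"dimension mismatch: map {all_features.data.shape} vs "
            f"mask {fiber_mask.grid.shape}"
        )
    fib = fiber_mask.grid
    if dilate_radius_vox > 0:
        fib = binary_dilation(fib, iterations=dilate_radius_vox)
    data = np.where(fib, np.min(all_features.data), all_features.data)
    mesh = (data > meshing_threshold) if strict else (data >= meshing_threshold)
    mesh &= ~fib
    return BinaryMask(mesh, all_features.voxel_size_nm, all_features.origin_nm)


@dataclass
class OccupancyResult:
    """Voxel occupancy of the fiber and meshing features in one tomogram."""

    fiber_voxels: int
    meshing_voxels: int
    fiber_volume_nm3: float
    meshing_volume_nm3: float
    ratio_meshing_over_fiber: float  # NaN when no fiber voxels
    fiber_fraction: float
    meshing_fraction: float
    depth_um: float | None = None
    scale_number: int | None = None
    treatment: str | None = None

    def to_dict(self) -> dict:
        return {
            "fiber_voxels": self.fiber_voxels,
            "meshing_voxels": self.meshing_voxels,
            "fiber_volume_nm3": self.fiber_volume_nm3,
            "meshing_volume_nm3": self.meshing_volume_nm3,
            "ratio_meshing_over_fiber": self.ratio_meshing_over_fiber,
            "fiber_fraction": self.fiber_fraction,
            "meshing_fraction": self.meshing_fraction,
            "depth_um": self.depth_um,
            "scale": self.scale_number,
            "treatment": self.treatment,
        }


def occupancy_stats(
    fiber_mask: BinaryMask,
    meshing_mask: BinaryMask,
    context: TomogramContext | None = None,
) -> OccupancyResult:
    """Counts, volumes, meshing/fiber ratio and normalized fractions.

    Fractions are normalized to the total occupancy (fiber + meshing),
    so they sum to 1 whenever either feature is present.
    """
    if fiber_mask.grid.shape != meshing_mask.grid.shape:
        raise ValueError("masks must share a grid")
    if (fiber_mask.grid & meshing_mask.grid).any():
        raise ValueError("fiber and meshing masks overlap; they must be disjoint")
    nf, nm = fiber_mask.count, meshing_mask.count
    vv = fiber_mask.voxel_size_nm**3
    total = nf + nm
    ratio = nm / nf if nf > 0 else math.nan
    return OccupancyResult(
        fiber_voxels=nf,
        meshing_voxels=nm,
        fiber_volume_nm3=nf * vv,
        meshing_volume_nm3=nm * vv,
        ratio_meshing_over_fiber=ratio,
        fiber_fraction=nf / total if total else 0.0,
        meshing_fraction=nm / total if total else 0.0,
        depth_um=context.depth_um if context else None,
        scale_number=context.scale_number if context else None,
        treatment=context.treatment if context else None,
    )


def depth_profile(
    results: list[OccupancyResult],
    exclude: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order occupancy results by depth and summarize per condition.

    Returns (table, summary): the table is sorted by depth with an
    ``excluded`` flag for indices listed in ``exclude`` (honoured and
    logged, not silently dropped); the summary holds mean +/- sd of the
    meshing/fiber ratio per treatment over non-excluded rows.
    """
    if not results:
        raise ValueError("need at least one occupancy result")
    rows = []
    excluded = set(exclude or [])
    for i, r in enumerate(results):
        d = r.to_dict()
        d["excluded"] = i in excluded
        rows.append(d)
    table = pd.DataFrame(rows).sort_values("depth_um", na_position="last").reset_index(
        drop=True
    )
    kept = table[~table["excluded"]]
    summary = (
        kept.groupby("treatment", dropna=False)["ratio_meshing_over_fiber"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "ratio_mean", "std": "ratio_sd", "count": "n"})
    )
    return table, summary


def meshing_fiber_pipeline(
    fiber_map: DensityVolume,
    all_features_map: DensityVolume,
    fiber_threshold: float,
    meshing_threshold: float,
    context: TomogramContext | None = None,
    dilate_radius_vox: int = 0,
) -> tuple[OccupancyResult, BinaryMask, BinaryMask]:
    """Threshold, subtract and quantify in one call."""
    fib = binarize_map(fiber_map, fiber_threshold)
    mesh = subtract_fiber_mask(
        all_features_map, fib, meshing_threshold, dilate_radius_vox=dilate_radius_vox
    )
    return occupancy_stats(fib, mesh, context), fib, mesh
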