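"""Intensity-profile measurements: transect averaging, double
normalization, FWHM, and fluorescence ROI quantification.

The cross-sectional diameter of a fiber is measured by sampling
transects perpendicular to a path traced along the fiber (side-view
profile averaging), double-normalizing the averaged profile to [0, 1],
and reading the full width of the bell at half maximum with sub-pixel
(0.5 px) interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates


@dataclass
class Profile:
    """A 1D intensity profile; positions in px (possibly sub-pixel)."""

    positions: np.ndarray
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must be matching 1D arrays")
        if (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if self.normalized:
            lo, hi = self.intensities.min(), self.intensities.max()
            if abs(lo) > 1e-9 or abs(hi - 1.0) > 1e-9:
                raise ValueError("normalized profile must span exactly [0, 1]")


def double_normalize(values) -> np.ndarray:
    """Min-max normalize: v' = (v - min) / (max - min).

    The minimum maps to 0 and the maximum to 1, making profiles (or ROI
    means) comparable across images and conditions.  Affine-invariant:
    normalizing a*v + b (a > 0) gives the same result as normalizing v.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant input (max == min)")
    return (v - lo) / (hi - lo)


def normalize_profile(profile: Profile) -> Profile:
    return Profile(profile.positions, double_normalize(profile.intensities), True)


def sample_profile(
    data: np.ndarray,
    path_xy: np.ndarray,
    step_px: float = 1.0,
    length_px: int = 30,
    thickness_px: int = 10,
    path_z: float | None = None,
) -> Profile:
    """Average perpendicular transects along a path into one profile.

    At stations every ``step_px`` along the (x, y) polyline, a transect
    of ``length_px`` samples perpendicular to the local path direction
    is read by linear interpolation.  For a 3D volume the transect is
    additionally averaged over ``thickness_px`` planes along z centred
    on ``path_z``.  All transects are then averaged into one profile.
    """
    data = np.asarray(data, dtype=float)
    path = np.asarray(path_xy, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or path.shape[0] < 2:
        raise ValueError("path must be an (n, 2) polyline with n >= 2")
    is_volume = data.ndim == 3
    if is_volume and path_z is None:
        raise ValueError("path_z required for a 3D volume")
    if not is_volume and data.ndim != 2:
        raise ValueError("data must be a 2D image or 3D volume")

    # stations at uniform arc length
    seg = np.diff(path, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n_st = max(2, int(math.floor(s[-1] / step_px)) + 1)
    st_s = np.linspace(0.0, s[-1], n_st)
    sx = np.interp(st_s, s, path[:, 0])
    sy = np.interp(st_s, s, path[:, 1])
    # local tangents by central differences along the station sequence
    tx = np.gradient(sx)
    ty = np.gradient(sy)
    norm = np.hypot(tx, ty)
    if (norm == 0).any():
        raise ValueError("degenerate path: zero local direction at some station")
    tx, ty = tx / norm, ty / norm
    px, py = -ty, tx  # in-plane perpendicular

    offsets = np.arange(length_px) - (length_px - 1) / 2.0
    xs = sx[:, None] + px[:, None] * offsets[None, :]
    ys = sy[:, None] + py[:, None] * offsets[None, :]

    ny_ax, nx_ax = data.shape[-2], data.shape[-1]
    bad = (xs < 0) | (xs > nx_ax - 1) | (ys < 0) | (ys > ny_ax - 1)
    if bad.any():
        idx = sorted(set(np.where(bad)[0].tolist()))
        raise ValueError(f"path too close to border: stations {idx} sample outside the data")

    if is_volume:
        zoff = np.arange(thickness_px) - (thickness_px - 1) / 2.0
        zs = np.clip(path_z + zoff, 0, data.shape[0] - 1)
        acc = np.zeros_like(xs)
        for z in zs:
            coords = np.stack([np.full_like(xs, z), ys, xs])
            acc += map_coordinates(data, coords, order=1, mode="nearest")
        transects = acc / len(zs)
    else:
        coords = np.stack([ys, xs])
        transects = map_coordinates(data, coords, order=1, mode="nearest")

    return Profile(offsets, transects.mean(axis=0), normalized=False)


def fwhm(profile: Profile, upsample: float = 0.5) -> float:
    """Full width at half maximum of a single-peaked profile, in px.

    The profile is normalized to [0, 1] (if not already), resampled on
    an ``upsample``-px grid, and the width is taken between the
    outermost 0.5-crossings bracketing the global peak, each located by
    linear interpolation.  Raises if either flank never crosses 0.5
    (peak at the border).
    """
    if not profile.normalized:
        profile = normalize_profile(profile)
    x0, x1 = profile.positions[0], profile.positions[-1]
    n = int(round((x1 - x0) / upsample)) + 1
    x = np.linspace(x0, x1, n)
    y = np.interp(x, profile.positions, profile.intensities)
    ipeak = int(np.argmax(y))
    half = 0.5

    def crossing(lo_idx, hi_idx, rising):
        # outermost crossing: scan from the border toward the peak
        rng = range(lo_idx, hi_idx) if rising else range(hi_idx - 1, lo_idx - 1, -1)
        for i in rng:
            y0, y1 = y[i], y[i + 1]
            if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
                t = (half - y0) / (y1 - y0)
                return x[i] + t * (x[i + 1] - x[i])
        return None

    left = crossing(0, ipeak, rising=True)
    right = crossing(ipeak, n - 1, rising=False)
    if left is None or right is None:
        raise ValueError("no 0.5 crossing on one flank: peak touches the profile border")
    return float(right - left)


def roi_mean_intensity(
    image: np.ndarray, rois: np.ndarray | dict[str, np.ndarray]
) -> pd.DataFrame:
    """Mean intensity per ROI, double-normalized over the whole image.

    ``rois`` is either a labeled integer mask (0 = background) or a
    mapping of name -> boolean mask.  Raw ROI means are normalized with
    the global image min/max so conditions share one scale.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        raise ValueError("cannot normalize a constant image")
    if isinstance(rois, dict):
        items = rois.items()
    else:
        lab = np.asarray(rois)
        if lab.shape != img.shape:
            raise ValueError("ROI mask shape must match the image")
        items = [(str(v), lab == v) for v in np.unique(lab) if v != 0]
    rows = []
    for name, mask in items:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty")
        raw = float(img[mask].mean())
        rows.append(
            {"roi": name, "mean_raw": raw, "mean_normalized": (raw - lo) / (hi - lo)}
        )
    return pd.DataFrame(rows)
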