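"""2D cell morphometrics from outline images.

Epidermal cell aspect ratios are measured from light-microscopy cell
outline drawings: the outline mask is Gaussian-smoothed, skeletonized
to one-pixel walls, and every enclosed region becomes one cell whose
aspect ratio is the major/minor axis ratio of its second-moment
(inertia-equivalent) ellipse.  Regions touching the image border are
discarded as incomplete cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize
from skimage.segmentation import clear_border


def region_aspect_ratios(label_image: np.ndarray, min_area_px: int = 20) -> pd.DataFrame:
    """Aspect ratio of each labeled region from its second-moment ellipse."""
    rows = []
    for rp in regionprops(np.asarray(label_image)):
        if rp.area < min_area_px or rp.axis_minor_length == 0:
            continue
        rows.append(
            {
                "label": rp.label,
                "area_px": int(rp.area),
                "major_axis_px": rp.axis_major_length,
                "minor_axis_px": rp.axis_minor_length,
                "aspect_ratio": rp.axis_major_length / rp.axis_minor_length,
                "orientation_rad": rp.orientation,
            }
        )
    return pd.DataFrame(rows)


def cell_aspect_ratios(
    outline_image: np.ndarray,
    smooth_sigma_px: float = 2.0,
    binarize_level: float = 0.1,
    min_area_px: int = 20,
) -> pd.DataFrame:
    """Detect closed cells in an outline image and measure aspect ratios.

    Pipeline: binary outline mask -> Gaussian blur (sigma 2 px) ->
    re-binarize -> skeletonize -> label the enclosed regions -> per-region
    second-moment aspect ratio.  Border-touching regions (including the
    outer background) are removed.  Returns an empty table when no
    closed region survives.
    """
    img = np.asarray(outline_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("outline image must be 2D")
    mask = img > (0.5 * img.max() if img.max() > 1 else 0.5)
    blurred = gaussian_filter(mask.astype(float), smooth_sigma_px)
    walls = skeletonize(blurred > binarize_level)
    cells = label(~walls, connectivity=1)
    cells = clear_border(cells)
    return region_aspect_ratios(cells, min_area_px=min_area_px)


def brick_wall_mosaic(
    n_rows: int = 6,
    n_cols: int = 5,
    cell_height_px: int = 20,
    mean_aspect: float = 4.0,
    aspect_sd: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthetic brick-wall mosaic of cell outlines with known aspect ratios.

    Rows of rectangular cells with widths drawn so that the interior
    width/height ratio follows the requested distribution; rows are
    offset like brickwork.  Returns the outline image and a truth table
    (one row per drawn cell with its interior aspect ratio).
    """
    rng = np.random.default_rng(seed)
    h = cell_height_px
    width = int(round(n_cols * mean_aspect * (h - 1))) + 1
    height = n_rows * h + 1
    img = np.zeros((height, width), dtype=np.uint8)
    rows = []
    for r in range(n_rows):
        y0, y1 = r * h, (r + 1) * h
        img[y0, :] = 1
        img[y1, :] = 1
        img[y0 : y1 + 1, 0] = 1
        img[y0 : y1 + 1, -1] = 1
        # random widths tile the row exactly; the last cell absorbs the
        # remainder so every enclosed region appears in the truth table
        x, col = 0, 0
        min_w = int(1.2 * (h - 1)) + 1
        while True:
            aspect = max(1.2, rng.normal(mean_aspect, aspect_sd))
            w = int(round(aspect * (h - 1))) + 1
            remaining = (width - 1) - x
            if remaining - w < min_w + 1:
                w = remaining  # final cell of the row
            x2 = x + w
            img[y0 : y1 + 1, x2] = 1
            rows.append(
                {
                    "row": r,
                    "col": col,
                    "interior_w": w - 1,
                    "interior_h": h - 1,
                    "aspect_ratio": (w - 1) / (h - 1),
                }
            )
            if x2 >= width - 1:
                break
            x, col = x2, col + 1
    return img, pd.DataFrame(rows)
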