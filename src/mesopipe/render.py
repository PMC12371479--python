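"""Pixel-exact PNG rendering of metric maps.

Maps stay on their native pixel grid (optionally nearest-upscaled by an
integer factor); pixels outside the cortical mask are rendered transparent;
ROI outlines are drawn one pixel wide (the morphological boundary of each
mask).  Rendering is a display concern — all quantitative output stays in
TIFF/CSV.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image
from scipy import ndimage

from .roi_manager import ROISet

__all__ = ["render_map", "roi_boundaries"]


def roi_boundaries(mask: np.ndarray) -> np.ndarray:
    """1-px inner boundary of a boolean mask: pixels in the mask whose
    4-neighbourhood leaves it."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
    return mask & ~eroded


def render_map(map_2d: np.ndarray, out_png: str | Path,
               colormap: str = "viridis",
               symmetric: bool = False,
               rois: ROISet | None = None,
               mask: np.ndarray | None = None,
               scale: int = 1,
               vmin: float | None = None,
               vmax: float | None = None) -> Path:
    """Render a 2-D map to PNG on its own pixel grid.

    ``symmetric`` centers the color limits on zero (for subtraction maps);
    ``mask`` marks visible-cortex pixels (outside -> transparent, as are NaN
    pixels); ``rois`` adds 1-px white contours; ``scale`` upscales by an
    integer factor with nearest interpolation only.
    """
    m = np.asarray(map_2d, dtype=float)
    if m.ndim != 2:
        raise ValueError("map must be 2-D")
    H, W = m.shape
    if int(scale) != scale or scale < 1:
        raise ValueError("scale must be a positive integer")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError(f"mask shape {mask.shape} != map shape {(H, W)}")
    visible = np.isfinite(m) & (mask if mask is not None else True)

    finite = m[visible]
    if finite.size:
        lo = np.min(finite) if vmin is None else vmin
        hi = np.max(finite) if vmax is None else vmax
    else:
        lo, hi = 0.0, 1.0
    if symmetric:
        amp = max(abs(lo), abs(hi))
        lo, hi = -amp, amp
    if hi == lo:
        hi = lo + 1.0

    cmap = matplotlib.colormaps[colormap]
    norm = np.clip((np.nan_to_num(m, nan=lo) - lo) / (hi - lo), 0.0, 1.0)
    rgba = (cmap(norm) * 255).astype(np.uint8)
    rgba[..., 3] = np.where(visible, 255, 0)

    if rois is not None:
        for name, roi_mask in rois.masks((H, W)).items():
            edge = roi_boundaries(roi_mask)
            rgba[edge] = [255, 255, 255, 255]

    if scale > 1:
        rgba = np.repeat(np.repeat(rgba, scale, axis=0), scale, axis=1)
    out_png = Path(out_png)
    Image.fromarray(rgba, mode="RGBA").save(out_png)
    return out_png
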