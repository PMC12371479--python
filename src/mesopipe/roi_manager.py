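"""Regions of interest: creation, rasterization, combination and extraction.

ROIs are stored geometrically (point, circle, polygon) where possible so
they survive re-registration by transforming coordinates; threshold- and
mask-kind ROIs carry a boolean mask (run-length encoded in the JSON file).

Geometry convention: integer indices ARE pixel centers — pixel ``(r, c)``
has its center at coordinates ``(r, c)``.  Circles include boundary pixels
(distance <= radius); polygons use the even-odd rule with points on an edge
counted inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ImageStack

__all__ = [
    "ROI",
    "ROISet",
    "rasterize",
    "threshold_roi",
    "combine",
    "extract_traces",
    "save_rois",
    "load_rois",
    "rle_encode",
    "rle_decode",
]

ROI_KINDS = ("point", "circle", "polygon", "threshold", "mask")
ROISET_VERSION = "1"


@dataclass
class ROI:
    """One named region.  ``params`` depends on ``kind``:

    * ``point``: ``{"row": r, "col": c}``
    * ``circle``: ``{"center": [r, c], "radius": px}``
    * ``polygon``: ``{"vertices": [[r, c], ...]}``
    * ``threshold``: ``{"direction": "above"|"below", "cutoff": x,
      "mask": bool array}`` (mask frozen at creation from the source map)
    * ``mask``: ``{"mask": bool array}``
    """

    name: str
    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}")


def _point_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon with boundary points counted inside.

    Vectorised ray casting: a point is inside when a ray to +inf in the
    column direction crosses an odd number of edges; points lying exactly on
    an edge segment are inside regardless.
    """
    r, c = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # on-segment check (exact for the integer/float coords used in ROIs)
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        within = (np.minimum(r1, r2) - 1e-12 <= r) & (r <= np.maximum(r1, r2) + 1e-12) \
            & (np.minimum(c1, c2) - 1e-12 <= c) & (c <= np.maximum(c1, c2) + 1e-12)
        on_edge |= within & (np.abs(cross) < 1e-9)
        # crossing test on the half-open edge [r1, r2)
        cond = (r1 <= r) != (r2 <= r)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
        inside ^= cond & (c < c_int)
    return inside | on_edge


def rasterize(roi: ROI, frame_shape: tuple[int, int]) -> np.ndarray:
    """Deterministic boolean mask of ``frame_shape`` for any ROI kind.

    Raises if the ROI has no pixel inside the frame.
    """
    H, W = frame_shape
    mask = np.zeros((H, W), dtype=bool)
    if roi.kind == "point":
        r, c = int(roi.params["row"]), int(roi.params["col"])
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"ROI {roi.name!r}: point ({r},{c}) outside frame")
        mask[r, c] = True
    elif roi.kind == "circle":
        (r0, c0), radius = roi.params["center"], float(roi.params["radius"])
        rr, cc = np.mgrid[0:H, 0:W]
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
    elif roi.kind == "polygon":
        verts = np.asarray(roi.params["vertices"], dtype=float)
        if verts.ndim != 2 or len(verts) < 3:
            raise ValueError(f"ROI {roi.name!r}: polygon needs >= 3 vertices")
        rr, cc = np.mgrid[0:H, 0:W]
        pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        mask = _point_in_polygon(pts, verts).reshape(H, W)
    elif roi.kind in ("threshold", "mask"):
        m = np.asarray(roi.params["mask"], dtype=bool)
        if m.shape != (H, W):
            raise ValueError(
                f"ROI {roi.name!r}: stored mask {m.shape} vs frame {(H, W)}"
            )
        mask = m.copy()
    if not mask.any():
        raise ValueError(f"ROI {roi.name!r} rasterizes to an empty mask")
    return mask


def threshold_roi(map_2d: np.ndarray, direction: str, cutoff: float,
                  name: str) -> ROI:
    """ROI of pixels strictly above/below ``cutoff`` in a metric map."""
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    m = np.asarray(map_2d, dtype=float)
    mask = (m > cutoff) if direction == "above" else (m < cutoff)
    mask &= np.isfinite(m)
    if not mask.any():
        raise ValueError(
            f"threshold {direction} {cutoff} selects 0 pixels in map "
            f"(range {np.nanmin(m)}..{np.nanmax(m)})"
        )
    return ROI(name=name, kind="threshold",
               params={"direction": direction, "cutoff": float(cutoff), "mask": mask})


def combine(rois: list[ROI], op: str, frame_shape: tuple[int, int],
            aux_mask: np.ndarray | None = None,
            name: str = "combined") -> ROI:
    """Boolean combination of ROIs: ``merge`` (union), ``intersect``, or
    ``crop_to_mask`` (AND with ``aux_mask``, e.g. the visible-cortex mask)."""
    if not rois:
        raise ValueError("no ROIs to combine")
    masks = [rasterize(r, frame_shape) for r in rois]
    if op == "merge":
        out = np.logical_or.reduce(masks)
    elif op == "intersect":
        out = np.logical_and.reduce(masks)
    elif op == "crop_to_mask":
        if aux_mask is None:
            raise ValueError("crop_to_mask requires aux_mask")
        aux = np.asarray(aux_mask, dtype=bool)
        if aux.shape != frame_shape:
            raise ValueError("aux_mask shape must match frame shape")
        out = np.logical_or.reduce(masks) & aux
    else:
        raise ValueError(f"unknown combine op {op!r}")
    if not out.any():
        raise ValueError(f"combine({op}) produced an empty ROI")
    return ROI(name=name, kind="mask", params={"mask": out})


class ROISet:
    """An ordered collection of uniquely named ROIs."""

    def __init__(self, rois: list[ROI] | None = None):
        self._rois: list[ROI] = []
        for r in rois or []:
            self.add(r)

    def add(self, roi: ROI) -> None:
        if roi.name in self.names:
            raise ValueError(f"duplicate ROI name {roi.name!r}")
        self._rois.append(roi)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self._rois]

    def __iter__(self):
        return iter(self._rois)

    def __len__(self) -> int:
        return len(self._rois)

    def __getitem__(self, name: str) -> ROI:
        for r in self._rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def masks(self, frame_shape: tuple[int, int]) -> dict[str, np.ndarray]:
        return {r.name: rasterize(r, frame_shape) for r in self._rois}


def extract_traces(stack: ImageStack, rois: ROISet) -> pd.DataFrame:
    """Per-frame unweighted mean over each ROI's mask pixels.

    Returns a DataFrame ``time x roi_name``.  Missing (NaN) pixels are
    excluded frame by frame.
    """
    T, H, W = stack.shape
    data = stack.data.reshape(T, H * W).astype(np.float64)
    cols = {}
    for roi in rois:
        mask = rasterize(roi, (H, W)).ravel()
        block = data[:, mask]
        cols[roi.name] = np.nanmean(block, axis=1)
    return pd.DataFrame(cols, index=np.arange(T))


# ---------------------------------------------------------------------------
# persistence (JSON; masks run-length encoded)
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean mask (C-order; runs alternate starting False)."""
    arr = np.asarray(mask, dtype=bool)
    flat = arr.ravel()
    if flat.size == 0:
        return {"shape": list(arr.shape), "runs": []}
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [flat.size]])
    runs = [int(x) for x in ends - starts]
    if flat[0]:
        runs = [0] + runs
    return {"shape": list(arr.shape), "runs": runs}


def rle_decode(obj: dict) -> np.ndarray:
    shape = tuple(obj["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in obj["runs"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    if pos != flat.size:
        raise ValueError(f"RLE runs sum to {pos}, expected {flat.size}")
    return flat.reshape(shape)


def _roi_to_json(roi: ROI) -> dict:
    params = dict(roi.params)
    if "mask" in params:
        params["mask"] = rle_encode(params["mask"])
    return {"name": roi.name, "kind": roi.kind, "params": params}


def _roi_from_json(obj: dict) -> ROI:
    params = dict(obj["params"])
    if "mask" in params:
        params["mask"] = rle_decode(params["mask"])
    return ROI(name=obj["name"], kind=obj["kind"], params=params)


def save_rois(rois: ROISet, path: str | Path) -> Path:
    path = Path(path)
    obj = {"roiset_version": ROISET_VERSION,
           "rois": [_roi_to_json(r) for r in rois]}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_rois(path: str | Path) -> ROISet:
    obj = json.loads(Path(path).read_text())
    if obj.get("roiset_version") != ROISET_VERSION:
        raise ValueError(f"unknown roiset_version {obj.get('roiset_version')!r}")
    rois = [_roi_from_json(o) for o in obj["rois"]]
    return ROISet(rois)  # ROISet.add enforces unique names
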