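"""Resting-state functional connectivity.

Spontaneous widefield activity is summarised by Pearson correlation: a seed
trace against every pixel (seed-pixel correlation map) or all pairs of ROI
traces (connectivity matrix), optionally Fisher z-transformed
(``z = arctanh r``) to approximate normality before statistics.  A per-pixel
standard-deviation map quantifies overall fluctuation amplitude, and matrix
subtraction highlights connectivity change against a reference session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ImageStack
from .roi_manager import ROISet, extract_traces

__all__ = [
    "CorrelationMatrix",
    "seed_correlation_map",
    "correlation_matrix",
    "fisher_z",
    "sd_map",
    "matrix_subtract",
]

# identical traces give r == 1 exactly; clip before arctanh so z stays finite
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transformation ``arctanh(r)`` with r clipped to +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _pearson_vs_many(seed_trace: np.ndarray, traces: np.ndarray) -> np.ndarray:
    """Pearson r of one trace against columns of ``traces`` (T, P), NaN-pairwise."""
    ok_seed = np.isfinite(seed_trace)
    out = np.full(traces.shape[1], np.nan)
    col_nan = ~np.isfinite(traces).all(axis=0)
    # fast path: columns with no missing frames
    valid = ok_seed
    s = seed_trace[valid]
    s = s - s.mean()
    sn = np.sqrt((s ** 2).sum())
    block = traces[valid][:, ~col_nan]
    block = block - block.mean(axis=0)
    denom = sn * np.sqrt((block ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out[~col_nan] = np.where(denom > 0, (s @ block) / denom, np.nan)
    for j in np.where(col_nan)[0]:
        both = ok_seed & np.isfinite(traces[:, j])
        if both.sum() < 3:
            continue
        a, b = seed_trace[both], traces[both, j]
        a, b = a - a.mean(), b - b.mean()
        d = np.sqrt((a ** 2).sum() * (b ** 2).sum())
        out[j] = (a @ b) / d if d > 0 else np.nan
    return np.clip(out, -1.0, 1.0)  # guards float round-off; NaN passes through


def seed_correlation_map(stack: ImageStack,
                         seed: tuple[int, int] | np.ndarray,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation of a seed trace with every pixel trace.

    ``seed`` is either a ``(row, col)`` pixel or a boolean ROI mask (the seed
    trace is then the unweighted mean over seed pixels).  Pixels outside
    ``mask`` come back NaN.  The map at the seed pixel itself is 1 by
    definition.
    """
    T, H, W = stack.shape
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    data = stack.data.reshape(T, H * W).astype(np.float64)
    if isinstance(seed, tuple):
        r0, c0 = seed
        if not (0 <= r0 < H and 0 <= c0 < W):
            raise ValueError(f"seed {seed} outside {H}x{W} frame")
        seed_trace = data[:, r0 * W + c0].copy()
    else:
        seed_mask = np.asarray(seed, dtype=bool)
        if seed_mask.shape != (H, W) or not seed_mask.any():
            raise ValueError("seed mask must be a nonempty (H, W) boolean array")
        seed_trace = np.nanmean(data[:, seed_mask.ravel()], axis=1)
    if np.nanstd(seed_trace) == 0:
        raise ValueError("seed trace is constant")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if isinstance(seed, tuple) and not mask[seed]:
            raise ValueError("seed lies outside the mask")
    r = _pearson_vs_many(seed_trace, data).reshape(H, W)
    if mask is not None:
        r = np.where(mask, r, np.nan)
    return r


@dataclass
class CorrelationMatrix:
    """ROI-pair Pearson correlations with optional Fisher z.

    ``r`` is square, symmetric, unit diagonal.  ``z`` (if computed) is
    ``arctanh`` of the clipped r with a NaN diagonal.
    """

    roi_names: list[str]
    r: np.ndarray
    z: np.ndarray | None
    n_timepoints: int

    def save(self, basepath: str | Path) -> tuple[Path, Path]:
        """CSV with ROI-name header row/column plus a JSON sidecar."""
        base = Path(basepath)
        csv_path = base.with_suffix(".csv")
        pd.DataFrame(self.r, index=self.roi_names, columns=self.roi_names).to_csv(csv_path)
        meta_path = base.with_suffix(".json")
        meta_path.write_text(json.dumps(
            {"n_timepoints": self.n_timepoints, "fisher": self.z is not None,
             "roi_names": self.roi_names},
            indent=2, sort_keys=True) + "\n")
        return csv_path, meta_path

    @classmethod
    def load(cls, basepath: str | Path) -> "CorrelationMatrix":
        base = Path(basepath)
        df = pd.read_csv(base.with_suffix(".csv"), index_col=0)
        meta = json.loads(base.with_suffix(".json").read_text())
        r = df.to_numpy(dtype=float)
        z = None
        if meta.get("fisher"):
            z = fisher_z(r)
            np.fill_diagonal(z, np.nan)
        return cls(list(df.index), r, z, int(meta["n_timepoints"]))


def correlation_matrix(stack: ImageStack, rois: ROISet,
                       fisher: bool = False) -> CorrelationMatrix:
    """Pairwise Pearson correlation between ROI-mean traces.

    Each ROI trace is the unweighted mean over its mask pixels, per frame
    (missing pixels excluded).  With ``fisher=True`` the z matrix is attached.
    """
    T = stack.shape[0]
    if T < 3:
        raise ValueError("need at least 3 timepoints")
    traces = extract_traces(stack, rois)          # DataFrame time x roi
    names = list(traces.columns)
    X = traces.to_numpy(dtype=float)
    if (np.nanstd(X, axis=0) == 0).any():
        flat = [n for n, s in zip(names, np.nanstd(X, axis=0)) if s == 0]
        raise ValueError(f"constant ROI trace(s): {flat}")
    n = len(names)
    r = np.eye(n)
    for i in range(n):
        r[i, i + 1:] = _pearson_vs_many(X[:, i], X[:, i + 1:])
        r[i + 1:, i] = r[i, i + 1:]
    z = None
    if fisher:
        z = fisher_z(r)
        np.fill_diagonal(z, np.nan)
    return CorrelationMatrix(roi_names=names, r=r, z=z, n_timepoints=T)


def sd_map(stack: ImageStack, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel sample standard deviation over time (ddof=1).

    Larger spontaneous fluctuations mean more variability about the temporal
    mean; masked-out pixels come back NaN.
    """
    T, H, W = stack.shape
    if T < 2:
        raise ValueError("need at least 2 frames")
    out = np.nanstd(stack.data.astype(np.float64), axis=0, ddof=1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError("mask shape must match frame shape")
        out = np.where(mask, out, np.nan)
    return out


def matrix_subtract(m_a: CorrelationMatrix, m_ref: CorrelationMatrix,
                    use_z: bool = False) -> np.ndarray:
    """Elementwise ``m_a - m_ref`` in r-space (or z-space), NaN diagonal.

    ROI names must match in the same order; a permuted matrix is an error,
    never silently reordered.
    """
    if m_a.roi_names != m_ref.roi_names:
        raise ValueError(
            f"ROI name/order mismatch: {m_a.roi_names} vs {m_ref.roi_names}"
        )
    if use_z:
        a = m_a.z if m_a.z is not None else fisher_z(m_a.r)
        b = m_ref.z if m_ref.z is not None else fisher_z(m_ref.r)
    else:
        a, b = m_a.r, m_ref.r
    out = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    np.fill_diagonal(out, np.nan)
    return out
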