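"""Within- and between-subject spatial alignment of recordings.

Recordings of the same animal over weeks drift by small translations,
rotations and magnification changes; vessel patterns make good anatomical
landmarks.  Alignment uses a similarity transform (rotation + isotropic
scale + translation), estimated either from user-picked landmark pairs
(closed-form least squares) or automatically by maximising the mutual
information between a moving and a reference frame.  Across subjects only
translation and scale apply, anchored on a named skull landmark (Bregma)
and the pixel ratio of each recording.

A transform ``T`` maps coordinates as ``T(p) = c + s R (p - c) + t`` with
``R`` the rotation by ``rotation_deg`` about center ``c`` (row/col order).
``apply_transform`` resamples by inverse mapping: ``out(p) = img(T^{-1}(p))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .core_io import ImageStack

__all__ = [
    "SimilarityTransform",
    "fit_landmarks",
    "apply_transform",
    "mutual_information",
    "register_automatic",
    "register_intersubject",
    "save_transform",
    "load_transform",
]

TFORM_VERSION = "1"


@dataclass
class SimilarityTransform:
    """Rotation + isotropic scale + translation about a center, in pixels."""

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)   # (dr, dc)
    center: tuple[float, float] = (0.0, 0.0)        # (row, col)

    def __post_init__(self) -> None:
        if not np.isfinite([self.rotation_deg, self.scale, *self.translation,
                            *self.center]).all():
            raise ValueError("transform parameters must be finite")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        self.translation = tuple(float(x) for x in self.translation)
        self.center = tuple(float(x) for x in self.center)

    @property
    def linear(self) -> np.ndarray:
        """2x2 matrix ``s*R`` acting on (row, col) offsets."""
        th = math.radians(self.rotation_deg)
        return self.scale * np.array([[math.cos(th), -math.sin(th)],
                                      [math.sin(th), math.cos(th)]])

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` (row, col) coordinates forward."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (p - c) @ self.linear.T + c + t

    def inverse(self) -> "SimilarityTransform":
        """Closed-form inverse with the same center."""
        A_inv = np.linalg.inv(self.linear)
        t_new = -A_inv @ np.asarray(self.translation)
        return SimilarityTransform(
            rotation_deg=-self.rotation_deg,
            scale=1.0 / self.scale,
            translation=tuple(t_new),
            center=self.center,
        )

    def compose(self, first: "SimilarityTransform") -> "SimilarityTransform":
        """``self o first``: apply ``first`` then ``self``.

        The result is re-expressed about ``self.center``.
        """
        A = self.linear @ first.linear
        # full affine: x -> A x + b  from composing the two center forms
        b = (self.apply_points(first.apply_points(np.zeros((1, 2))))[0]
             - A @ np.zeros(2))
        scale = float(np.sqrt(np.linalg.det(A)))
        rot = math.degrees(math.atan2(A[1, 0], A[0, 0]))
        c = np.asarray(self.center)
        t = b - c + A @ c
        return SimilarityTransform(rotation_deg=rot, scale=scale,
                                   translation=tuple(t), center=self.center)


def fit_landmarks(src_points: np.ndarray, dst_points: np.ndarray,
                  center: tuple[float, float] = (0.0, 0.0)
                  ) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity from matched landmark pairs (Umeyama).

    Minimises ``sum ||T(src) - dst||^2`` over rotation, isotropic scale and
    translation.  Returns the transform (re-expressed about ``center``) and
    the RMS residual.  Needs >= 2 non-coincident pairs.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2 or src.shape[1] != 2:
        raise ValueError("need matching lists of >= 2 (row, col) point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = (xs ** 2).sum() / len(src)
    if var_s == 0:
        raise ValueError("source landmarks are all coincident")
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    t_affine = mu_d - scale * R @ mu_s
    rot = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    c = np.asarray(center, dtype=float)
    translation = t_affine - c + scale * R @ c
    tform = SimilarityTransform(rotation_deg=rot, scale=scale,
                                translation=tuple(translation), center=tuple(c))
    rms = float(np.sqrt(((tform.apply_points(src) - dst) ** 2).sum(axis=1).mean()))
    return tform, rms


def apply_transform(stack_or_frame: ImageStack | np.ndarray,
                    t: SimilarityTransform,
                    interpolation: str = "bilinear"):
    """Resample an image (or every frame of a stack) under ``t``.

    Inverse-mapping: output pixel ``p`` samples the input at ``T^{-1}(p)``.
    Out-of-bounds pixels become NaN (missing); shape is preserved.
    """
    orders = {"nearest": 0, "bilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}")
    order = orders[interpolation]

    def warp_frame(img: np.ndarray) -> np.ndarray:
        H, W = img.shape
        rr, cc = np.mgrid[0:H, 0:W]
        coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        src = t.inverse().apply_points(coords)
        out = ndimage.map_coordinates(
            img.astype(np.float64), [src[:, 0], src[:, 1]],
            order=order, mode="constant", cval=np.nan,
        )
        return out.reshape(H, W)

    if isinstance(stack_or_frame, ImageStack):
        warped = np.stack([warp_frame(f) for f in stack_or_frame.data])
        return stack_or_frame.with_data(
            warped, stage="apply_transform",
            params={"rotation_deg": t.rotation_deg, "scale": t.scale,
                    "translation": list(t.translation), "center": list(t.center),
                    "interpolation": interpolation})
    frame = np.asarray(stack_or_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a 2-D frame or an ImageStack")
    return warp_frame(frame)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Histogram mutual information of two images over their finite overlap."""
    a, b = np.asarray(a, dtype=float).ravel(), np.asarray(b, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 16:
        return 0.0
    hist, _, _ = np.histogram2d(a[ok], b[ok], bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def _mi_of_params(params: np.ndarray, moving: np.ndarray, reference: np.ndarray,
                  center: tuple[float, float], bins: int) -> float:
    rot, scale, dr, dc = params
    if scale <= 0.05:
        return 0.0
    t = SimilarityTransform(rotation_deg=rot, scale=scale,
                            translation=(dr, dc), center=center)
    return mutual_information(apply_transform(moving, t, "bilinear"),
                              reference, bins=bins)


def _translation_by_xcorr(moving: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Integer-pixel translation estimate via FFT cross-correlation."""
    def prep(x):
        x = np.asarray(x, dtype=float)
        fill = np.nanmean(x) if np.isfinite(x).any() else 0.0
        x = np.where(np.isfinite(x), x, fill)
        return x - x.mean()
    f = np.fft.rfft2(prep(reference)) * np.conj(np.fft.rfft2(prep(moving)))
    corr = np.fft.irfft2(f, s=reference.shape)
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    dr, dc = idx
    H, W = reference.shape
    if dr > H // 2:
        dr -= H
    if dc > W // 2:
        dc -= W
    return float(dr), float(dc)


def register_automatic(moving: np.ndarray, reference: np.ndarray,
                       init: SimilarityTransform | None = None,
                       bins: int = 32,
                       rotation_range_deg: float = 15.0,
                       scale_range: float = 0.10,
                       ) -> tuple[SimilarityTransform, float]:
    """Intensity-based similarity registration maximising mutual information.

    A coarse, deterministic grid over rotation and scale (translation per
    grid point estimated by FFT cross-correlation) seeds a Nelder-Mead
    refinement of (rotation, scale, dr, dc).  The initialization (``init``
    or identity) is always kept as a candidate, so the returned transform
    never has lower MI than it.  Returns ``(transform, mi)`` with the
    transform satisfying ``apply_transform(moving, transform) ~ reference``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share shape")
    for name, img in (("moving", moving), ("reference", reference)):
        finite = img[np.isfinite(img)]
        if finite.size == 0 or finite.std() == 0:
            raise ValueError(f"{name} image is constant")
    H, W = reference.shape
    center = ((H - 1) / 2.0, (W - 1) / 2.0)

    candidates: list[np.ndarray] = []
    if init is not None:
        candidates.append(np.array([init.rotation_deg, init.scale,
                                    *init.translation]))
    candidates.append(np.array([0.0, 1.0, 0.0, 0.0]))
    for rot in np.linspace(-rotation_range_deg, rotation_range_deg, 13):
        for scale in np.linspace(1 - scale_range, 1 + scale_range, 5):
            t = SimilarityTransform(rotation_deg=rot, scale=scale,
                                    center=center)
            warped = apply_transform(moving, t, "bilinear")
            dr, dc = _translation_by_xcorr(warped, reference)
            candidates.append(np.array([rot, scale, dr, dc]))

    scored = [(_mi_of_params(p, moving, reference, center, bins), i, p)
              for i, p in enumerate(candidates)]
    scored.sort(key=lambda s: (-s[0], s[1]))
    best_mi, _, best = scored[0]

    # refine the leading candidates; coarse MI ranking can be deceived by
    # a local optimum, so a few starts are cheap insurance
    for _, _, start in scored[:4]:
        res = optimize.minimize(
            lambda p: -_mi_of_params(p, moving, reference, center, bins),
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 400},
        )
        if -res.fun > best_mi:
            best, best_mi = res.x, -res.fun
    t = SimilarityTransform(rotation_deg=float(best[0]), scale=float(best[1]),
                            translation=(float(best[2]), float(best[3])),
                            center=center)
    return t, float(best_mi)


def register_intersubject(ref_points: dict[str, tuple[float, float]],
                          target_points: dict[str, tuple[float, float]],
                          ref_pixel_ratio: float,
                          target_pixel_ratio: float,
                          anchor: str = "bregma") -> SimilarityTransform:
    """Translation + scale alignment across subjects (rotation fixed at 0).

    ``*_pixel_ratio`` is pixels per physical unit (e.g. px/mm);
    ``scale = target_ratio / ref_ratio``.  The returned transform maps
    reference-grid coordinates to target coordinates with the named anchor
    point (e.g. Bregma) fixed — it is the pull-back used directly by
    inverse-mapping resampling of the target recording onto the reference
    grid: ``registered = apply_transform(target, T.inverse())``.
    """
    if ref_pixel_ratio <= 0 or target_pixel_ratio <= 0:
        raise ValueError("pixel ratios must be positive")
    if anchor not in ref_points or anchor not in target_points:
        raise ValueError(
            f"anchor {anchor!r} missing (ref has {sorted(ref_points)}, "
            f"target has {sorted(target_points)})"
        )
    scale = target_pixel_ratio / ref_pixel_ratio
    p_ref = np.asarray(ref_points[anchor], dtype=float)
    p_tgt = np.asarray(target_points[anchor], dtype=float)
    # T(p) = scale * (p - p_ref) + p_tgt, expressed in center form about p_ref
    return SimilarityTransform(
        rotation_deg=0.0,
        scale=scale,
        translation=tuple(p_tgt - p_ref),
        center=tuple(p_ref),
    )


def save_transform(t: SimilarityTransform, path: str | Path) -> Path:
    """Persist a transform as ``tform_info.json``-style file (exact round trip)."""
    path = Path(path)
    obj = {"schema_version": TFORM_VERSION, **asdict(t)}
    obj["translation"] = list(obj["translation"])
    obj["center"] = list(obj["center"])
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def load_transform(path: str | Path) -> SimilarityTransform:
    obj = json.loads(Path(path).read_text())
    if obj.get("schema_version") != TFORM_VERSION:
        raise ValueError(f"unknown schema_version {obj.get('schema_version')!r}")
    return SimilarityTransform(
        rotation_deg=float(obj["rotation_deg"]),
        scale=float(obj["scale"]),
        translation=tuple(obj["translation"]),
        center=tuple(obj["center"]),
    )
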