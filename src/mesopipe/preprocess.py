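"""Per-recording signal cleaning.

Widefield fluorescence of calcium indicators is contaminated by hemodynamics:
absorption by blood changes with blood volume and oxygenation, modulating
both the excitation and emission light.  With simultaneously acquired
reflectance channels the artifact can be removed by pixel-wise linear
regression of the fluorescence trace on the reflectance traces (the default
here), or by a ratiometric division.  Reflectance at two or more wavelengths
also supports estimating oxy-/deoxy-hemoglobin concentration changes through
the modified Beer-Lambert law.

The remaining stages are the usual widefield toolkit: global-signal
regression, zero-phase Butterworth temporal filtering, and dF/F
normalisation.  Every stage is shape- and metadata-preserving and appends
itself to the stack's audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import ImageStack

__all__ = [
    "HemoRegressionResult",
    "HemoConcentrations",
    "SpectraConfig",
    "DEFAULT_SPECTRA",
    "regress_hemodynamics",
    "ratiometric_correction",
    "beer_lambert",
    "global_signal_regression",
    "temporal_filter",
    "normalize_dff",
]


# ---------------------------------------------------------------------------
# hemodynamic regression
# ---------------------------------------------------------------------------

@dataclass
class HemoRegressionResult:
    """Output of :func:`regress_hemodynamics`.

    ``coefficients`` has shape ``(H, W, n_reflectance + 1)`` — per-pixel OLS
    slopes for each reflectance channel followed by the intercept.
    ``r_squared`` is the per-pixel coefficient of determination.
    """

    corrected: ImageStack
    coefficients: np.ndarray
    r_squared: np.ndarray


def _check_same_shape(stacks: list[ImageStack], ref: ImageStack) -> None:
    for s in stacks:
        if s.shape != ref.shape:
            raise ValueError(f"shape mismatch: {s.shape} vs {ref.shape}")


def regress_hemodynamics(fluo: ImageStack,
                         reflectance: list[ImageStack]) -> HemoRegressionResult:
    """Remove hemodynamic artifacts by per-pixel OLS on the reflectance traces.

    For each pixel the fluorescence trace is regressed on
    ``[1, refl_1, ..., refl_k]``; the corrected trace is the residual with the
    pixel's temporal mean restored (so dF/F stays computable downstream).
    Pixels whose reflectance traces are all constant degrade to an
    intercept-only fit (corrected == input) with a warning.
    """
    if not reflectance:
        raise ValueError("at least one reflectance channel is required")
    _check_same_shape(reflectance, fluo)
    T, H, W = fluo.shape
    k = len(reflectance)
    y = fluo.data.reshape(T, H * W).astype(np.float64)
    X = np.empty((T, H * W, k + 1))
    for i, r in enumerate(reflectance):
        X[:, :, i] = r.data.reshape(T, H * W)
    X[:, :, k] = 1.0

    var = X[:, :, :k].var(axis=0)           # (P, k)
    n_degenerate = int((var.max(axis=1) == 0).sum()) if k else 0
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} pixel(s) have constant reflectance traces; "
            "falling back to intercept-only fit there",
            RuntimeWarning,
        )

    # batched least squares via pseudoinverse of (P, T, k+1) designs;
    # pinv also covers rank-deficient (constant-regressor) pixels
    Xp = np.transpose(X, (1, 0, 2))         # (P, T, k+1)
    nan_pix = np.where(np.isnan(Xp).any(axis=(1, 2)) | np.isnan(y.T).any(axis=1))[0]
    Xw, yw = Xp, y
    if nan_pix.size:                         # missing frames: pairwise deletion
        Xw, yw = Xp.copy(), y.copy()
        Xw[nan_pix] = np.nan_to_num(Xw[nan_pix], nan=0.0)
        yw[:, nan_pix] = np.nan_to_num(yw[:, nan_pix], nan=0.0)
    beta = np.linalg.pinv(Xw) @ np.transpose(yw)[:, :, None]   # (P, k+1, 1)
    beta = beta[:, :, 0]
    for p in nan_pix:                        # refit on valid frames only
        valid = np.isfinite(Xp[p]).all(axis=1) & np.isfinite(y[:, p])
        if valid.sum() > k:
            beta[p] = np.linalg.pinv(Xp[p][valid]) @ y[valid, p]
    fitted = np.einsum("ptk,pk->pt", Xp, beta)
    resid = y.T - fitted                     # (P, T)
    mean = np.nanmean(y, axis=0)             # (P,)
    corrected = (resid + mean[:, None]).T.reshape(T, H, W)

    ss_res = np.nansum(resid ** 2, axis=1)
    ss_tot = np.nansum((y - mean) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    out = fluo.with_data(
        corrected.astype(fluo.data.dtype, copy=False),
        stage="regress_hemodynamics",
        params={"n_reflectance": k,
                "channels": [r.meta.channel_name for r in reflectance]},
    )
    return HemoRegressionResult(
        corrected=out,
        coefficients=beta.reshape(H, W, k + 1),
        r_squared=r2.reshape(H, W),
    )


def ratiometric_correction(fluo: ImageStack, reflectance: ImageStack) -> ImageStack:
    """Ratiometric hemodynamic correction.

    ``out[t] = (F[t]/mean_t F) / (R[t]/mean_t R)`` per pixel — a unitless
    normalised ratio in which any multiplicative artifact shared by the two
    channels cancels.  Requires strictly positive values.
    """
    _check_same_shape([reflectance], fluo)
    f, r = fluo.data, reflectance.data
    if (f <= 0).any() or (r <= 0).any():
        raise ValueError("ratiometric correction requires strictly positive stacks")
    out = (f / f.mean(axis=0)) / (r / r.mean(axis=0))
    return fluo.with_data(out, stage="ratiometric_correction",
                          params={"reflectance": reflectance.meta.channel_name})


# ---------------------------------------------------------------------------
# modified Beer-Lambert hemoglobin estimation
# ---------------------------------------------------------------------------

@dataclass
class SpectraConfig:
    """Wavelength-dependent constants for the modified Beer-Lambert model.

    ``extinction_hbo``/``extinction_hbr`` are molar extinction coefficients
    in 1/(uM*cm); ``pathlength_cm`` is the mean photon pathlength through
    tissue at each wavelength.  The shipped defaults cover common LED bands
    (green / amber / red); they are a starting point meant to be edited to
    the actual illumination and camera spectra of a rig.
    """

    wavelengths_nm: tuple[float, ...]
    extinction_hbo: tuple[float, ...]
    extinction_hbr: tuple[float, ...]
    pathlength_cm: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        if not (len(self.extinction_hbo) == len(self.extinction_hbr)
                == len(self.pathlength_cm) == n):
            raise ValueError("spectra arrays must all have the same length")

    def design(self, wavelengths: list[float]) -> np.ndarray:
        """Rows ``[eps_HbO * D, eps_HbR * D]`` for the requested wavelengths."""
        rows = []
        for wl in wavelengths:
            try:
                i = self.wavelengths_nm.index(wl)
            except ValueError:
                raise ValueError(f"spectra config has no entry for {wl} nm") from None
            d = self.pathlength_cm[i]
            rows.append([self.extinction_hbo[i] * d, self.extinction_hbr[i] * d])
        E = np.asarray(rows, dtype=np.float64)
        if len(rows) >= 2 and np.linalg.matrix_rank(E) < 2:
            raise ValueError("singular Beer-Lambert design: extinction columns proportional")
        return E


# extinction coefficients approximated from tabulated hemoglobin spectra,
# converted to 1/(uM*cm); pathlengths are nominal tissue values per band
DEFAULT_SPECTRA = SpectraConfig(
    wavelengths_nm=(525.0, 590.0, 625.0),
    extinction_hbo=(0.0390, 0.0145, 0.0015),
    extinction_hbr=(0.0410, 0.0380, 0.0055),
    pathlength_cm=(0.050, 0.060, 0.300),
)


@dataclass
class HemoConcentrations:
    """Oxy-/deoxy-hemoglobin concentration changes (uM, relative to baseline)."""

    delta_hbo: ImageStack
    delta_hbr: ImageStack
    spectra_config: SpectraConfig = field(default_factory=lambda: DEFAULT_SPECTRA)


def beer_lambert(reflectance: list[ImageStack],
                 spectra_config: SpectraConfig = DEFAULT_SPECTRA,
                 baseline_frames: tuple[int, int] | None = None) -> HemoConcentrations:
    """Estimate delta-HbO / delta-HbR from multi-wavelength reflectance.

    Per pixel and frame the optical-density change is
    ``dOD(lambda, t) = -ln(R(lambda, t) / R_baseline(lambda))`` with
    ``R_baseline`` the mean over ``baseline_frames`` (default: whole trace);
    concentrations solve the least-squares system
    ``dOD = [eps_HbO*D, eps_HbR*D] @ [dHbO, dHbR]`` across wavelengths.
    """
    if len(reflectance) < 2:
        raise ValueError("at least two wavelengths are required")
    ref0 = reflectance[0]
    _check_same_shape(reflectance, ref0)
    wavelengths = []
    for s in reflectance:
        if s.meta.wavelength_nm is None:
            raise ValueError(f"channel {s.meta.channel_name!r} has no wavelength_nm")
        wavelengths.append(s.meta.wavelength_nm)
    E = spectra_config.design(wavelengths)          # (n_lambda, 2)

    T, H, W = ref0.shape
    sl = slice(*baseline_frames) if baseline_frames is not None else slice(None)
    dod = np.empty((len(reflectance), T, H * W))
    for i, s in enumerate(reflectance):
        R = s.data.reshape(T, H * W).astype(np.float64)
        if (R <= 0).any():
            raise ValueError("reflectance must be strictly positive")
        dod[i] = -np.log(R / R[sl].mean(axis=0))
    # least squares across wavelengths for every (t, pixel) at once
    sol = np.linalg.pinv(E) @ dod.reshape(len(reflectance), -1)
    dhbo = sol[0].reshape(T, H, W)
    dhbr = sol[1].reshape(T, H, W)

    def as_stack(arr: np.ndarray, name: str) -> ImageStack:
        st = ref0.with_data(arr, stage="beer_lambert",
                            params={"wavelengths_nm": wavelengths, "output": name})
        st.meta.channel_name = name
        return st

    return HemoConcentrations(
        delta_hbo=as_stack(dhbo, "delta_hbo"),
        delta_hbr=as_stack(dhbr, "delta_hbr"),
        spectra_config=spectra_config,
    )


# ---------------------------------------------------------------------------
# global-signal regression, temporal filter, dF/F
# ---------------------------------------------------------------------------

def global_signal_regression(stack: ImageStack,
                             mask: np.ndarray | None = None,
                             mode: str = "regress") -> ImageStack:
    """Remove the spatially averaged common signal from every pixel trace.

    ``g(t)`` is the mean over (masked) pixels.  The default fits a per-pixel
    beta — each trace is regressed on ``[1, g]`` and replaced by its residual
    plus its original mean, leaving it uncorrelated with ``g``.
    ``mode="subtract"`` removes ``g - mean(g)`` directly instead.
    """
    T, H, W = stack.shape
    data = stack.data.reshape(T, H * W).astype(np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError("mask shape must match frame shape")
        if not mask.any():
            raise ValueError("mask is empty")
        g = np.nanmean(data[:, mask.ravel()], axis=1)
    else:
        g = np.nanmean(data, axis=1)

    mean = data.mean(axis=0)
    if mode == "subtract":
        out = data - (g - g.mean())[:, None]
    elif mode == "regress":
        gc = g - g.mean()
        denom = (gc ** 2).sum()
        if denom == 0:
            out = data.copy()
        else:
            beta = (gc @ (data - mean)) / denom      # (P,)
            out = data - gc[:, None] * beta[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return stack.with_data(out.reshape(T, H, W), stage="global_signal_regression",
                           params={"mode": mode, "masked": mask is not None})


def temporal_filter(stack: ImageStack,
                    low_hz: float | None = None,
                    high_hz: float | None = None,
                    order: int = 4) -> ImageStack:
    """Zero-phase Butterworth filter along the time axis of every pixel.

    ``low_hz``/``high_hz`` are the band edges; give only one for a pure
    high-pass or low-pass.  Filtering is forward-backward (``sosfiltfilt``)
    so no phase lag is introduced.  High-/band-pass removes DC, after which
    each pixel's temporal mean is restored.
    """
    if low_hz is None and high_hz is None:
        raise ValueError("at least one of low_hz / high_hz is required")
    nyq = stack.frame_rate_hz / 2.0
    for name, v in (("low_hz", low_hz), ("high_hz", high_hz)):
        if v is not None and not (0 < v < nyq):
            raise ValueError(f"{name}={v} outside (0, Nyquist={nyq})")
    if low_hz is not None and high_hz is not None:
        if not low_hz < high_hz:
            raise ValueError("low_hz must be < high_hz")
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=stack.frame_rate_hz, output="sos")
        restore_mean = True
    elif low_hz is not None:
        sos = signal.butter(order, low_hz, btype="highpass",
                            fs=stack.frame_rate_hz, output="sos")
        restore_mean = True
    else:
        sos = signal.butter(order, high_hz, btype="lowpass",
                            fs=stack.frame_rate_hz, output="sos")
        restore_mean = False

    T, H, W = stack.shape
    data = stack.data.reshape(T, H * W).astype(np.float64)
    out = signal.sosfiltfilt(sos, data, axis=0)
    if restore_mean:
        out = out - out.mean(axis=0) + data.mean(axis=0)
    return stack.with_data(out.reshape(T, H, W), stage="temporal_filter",
                           params={"low_hz": low_hz, "high_hz": high_hz, "order": order})


def normalize_dff(stack: ImageStack,
                  baseline: str = "whole_trace",
                  frame_range: tuple[int, int] | None = None) -> ImageStack:
    """dF/F normalisation: ``(F - F0) / F0`` per pixel, unitless.

    ``baseline="whole_trace"`` uses each pixel's temporal mean as F0;
    ``baseline="frame_range"`` uses the mean over ``frame_range`` (half-open
    frame interval).  F0 must be strictly positive everywhere.
    """
    data = stack.data.astype(np.float64)
    if baseline == "whole_trace":
        f0 = np.nanmean(data, axis=0)
    elif baseline == "frame_range":
        if frame_range is None:
            raise ValueError("frame_range baseline requires the range argument")
        a, b = frame_range
        if not (0 <= a < b <= stack.shape[0]):
            raise ValueError(f"frame_range {frame_range} outside recording")
        f0 = np.nanmean(data[a:b], axis=0)
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    n_bad = int((~(f0 > 0)).sum())
    if n_bad:
        raise ValueError(f"baseline F0 <= 0 at {n_bad} pixel(s)")
    out = (data - f0) / f0
    return stack.with_data(out, stage="normalize_dff",
                           params={"baseline": baseline, "frame_range": frame_range})
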