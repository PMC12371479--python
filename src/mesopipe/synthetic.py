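"""Synthetic recordings with machine-readable ground truth.

Every generator emulates one aspect of an interleaved-illumination widefield
experiment at desk scale (default 64x64 px, hundreds to a couple thousand
frames) and returns the truth needed to verify the corresponding analysis
stage:

* :func:`make_hemo_recording` — fluorescence built as a known linear mixture
  of reflectance channels plus a clean neural signal, for hemodynamic
  regression;
* :func:`make_evoked_recording` — Gaussian-blob responses with a
  double-exponential time course at stated event onsets, with analytic
  peak/latency/AUC truth;
* :func:`make_connected_recording` — region traces sharing a latent factor,
  with the closed-form inter-region correlation;
* :func:`make_vessel_pair` — a vessel-like image and a copy displaced by a
  known similarity transform, for registration.

All generators are bit-deterministic for a fixed seed on one platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import EventTable, ImageStack, RecordingMeta
from .registration import SimilarityTransform, apply_transform

__all__ = [
    "HemoSpec",
    "EvokedSpec",
    "ConnectivitySpec",
    "VesselSpec",
    "make_hemo_recording",
    "make_evoked_recording",
    "evoked_truth_metrics",
    "make_vessel_frame",
    "make_connected_recording",
    "make_vessel_pair",
    "response_kernel",
    "kernel_peak_time",
]


def _meta(spec, channel: str, wavelength: float | None = None) -> RecordingMeta:
    return RecordingMeta(
        frame_rate_hz=spec.frame_rate_hz,
        height_px=spec.height,
        width_px=spec.width,
        n_frames=spec.n_frames,
        channel_name=channel,
        wavelength_nm=wavelength,
    )


# ---------------------------------------------------------------------------
# hemodynamic mixture
# ---------------------------------------------------------------------------

@dataclass
class HemoSpec:
    """Conditions for the hemodynamic-mixture generator.

    Reflectance channels fluctuate around a baseline of 1 (sinusoidal
    hemodynamic artifact with a spatially varying weight); coupling
    coefficients per channel are drawn uniformly from ``coupling_range``;
    the clean neural signal is a sinusoid at a distinct frequency,
    orthogonal to the artifacts over the recording, so the generative
    coefficients are exactly identifiable.  ``noise_sigma`` is the
    per-pixel, per-frame Gaussian sensor noise on the fluorescence.

    The default artifact amplitude (10% of baseline) is set so the coupling
    coefficients are estimable at the default noise level within a 100 s
    recording: the OLS standard error per coefficient is roughly
    ``noise_sigma / (artifact SD * sqrt(T))``, which must sit well below the
    coefficient scale for recovery to be meaningful.
    """

    frame_rate_hz: float = 10.0
    n_frames: int = 1000
    height: int = 64
    width: int = 64
    n_reflectance: int = 2
    coupling_range: tuple[float, float] = (0.2, 0.8)
    artifact_amplitude: float = 0.10
    artifact_weight_range: tuple[float, float] = (0.75, 1.25)
    clean_amplitude: float = 0.12
    clean_weight_range: tuple[float, float] = (0.5, 1.5)
    noise_sigma: float = 0.01
    seed: int = 0


def _integer_cycle_freqs(n: int, n_frames: int, rate: float) -> list[float]:
    """Frequencies with an integer number of cycles over the recording,
    spread over (0.05, 0.4) x Nyquist so distinct channels stay orthogonal."""
    duration = n_frames / rate
    base_cycles = max(3, int(0.02 * n_frames))
    return [(base_cycles + 7 * i) / duration for i in range(n)]


def make_hemo_recording(spec: HemoSpec = HemoSpec()
                        ) -> tuple[ImageStack, list[ImageStack], dict]:
    """Fluorescence = sum_i beta_i * reflectance_i + clean + noise, per pixel.

    Returns ``(fluo, reflectance_list, truth)`` where truth holds
    ``coefficients`` (H, W, n_reflectance), ``intercept`` (H, W), and
    ``clean`` — the (T, H, W) noise-free neural signal.
    """
    rng = np.random.default_rng(spec.seed)
    T, H, W = spec.n_frames, spec.height, spec.width
    t = np.arange(T) / spec.frame_rate_hz

    freqs = _integer_cycle_freqs(spec.n_reflectance + 1, T, spec.frame_rate_hz)
    refl_stacks, refl_data = [], []
    for i in range(spec.n_reflectance):
        # distinct integer-cycle harmonics stay orthogonal for any phase
        phase = rng.uniform(0, 2 * math.pi)
        artifact = np.sin(2 * math.pi * freqs[i] * t + phase)
        weight = rng.uniform(*spec.artifact_weight_range, size=(H, W)) \
            * spec.artifact_amplitude
        data = 1.0 + artifact[:, None, None] * weight[None]
        meta = _meta(spec, channel=f"refl{i}", wavelength=(525.0, 625.0, 590.0)[i % 3])
        refl_stacks.append(ImageStack(data, meta))
        refl_data.append(data)

    lo, hi = spec.coupling_range
    beta = rng.uniform(lo, hi, size=(H, W, spec.n_reflectance))
    clean_weight = rng.uniform(*spec.clean_weight_range, size=(H, W)) \
        * spec.clean_amplitude
    clean_t = np.sin(2 * math.pi * freqs[-1] * t)
    clean = clean_t[:, None, None] * clean_weight[None]

    fluo = clean.copy()
    for i in range(spec.n_reflectance):
        fluo += beta[:, :, i][None] * refl_data[i]
    fluo += rng.normal(0.0, spec.noise_sigma, size=(T, H, W))
    fluo_stack = ImageStack(fluo, _meta(spec, "fluo"))

    truth = {
        "coefficients": beta,
        "intercept": np.zeros((H, W)),
        "clean": clean,
        "noise_sigma": spec.noise_sigma,
    }
    return fluo_stack, refl_stacks, truth


# ---------------------------------------------------------------------------
# evoked responses
# ---------------------------------------------------------------------------

def response_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Double-exponential response kernel ``(1 - e^{-t/rise}) e^{-t/decay}``,
    normalised to unit peak; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, (1 - np.exp(-np.maximum(t, 0) / rise_s))
                   * np.exp(-np.maximum(t, 0) / decay_s), 0.0)
    t_peak = kernel_peak_time(rise_s, decay_s)
    peak = (1 - math.exp(-t_peak / rise_s)) * math.exp(-t_peak / decay_s)
    return raw / peak


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Analytic peak time of the double-exponential kernel:
    ``rise * ln(1 + decay/rise)``."""
    return rise_s * math.log(1.0 + decay_s / rise_s)


def _kernel_integral(rise_s: float, decay_s: float, T: float) -> float:
    """Exact integral of the unnormalised kernel over [0, T]."""
    k = 1.0 / rise_s + 1.0 / decay_s
    return decay_s * (1 - math.exp(-T / decay_s)) - (1 - math.exp(-T * k)) / k


@dataclass
class EvokedSpec:
    """Conditions for the evoked-response generator.

    Each entry of ``responses`` places a Gaussian spatial blob whose time
    course follows the double-exponential kernel, starting ``onset_s`` after
    each matching event onset.  Amplitudes are in dF/F units (0.05 = 5%),
    typical of strong sensory responses; rise/decay constants are in the
    range of GCaMP6 kinetics.
    """

    frame_rate_hz: float = 10.0
    n_frames: int = 600
    height: int = 64
    width: int = 64
    responses: list[dict] = field(default_factory=lambda: [
        {"center": (20, 20), "sigma_px": 6.0, "amplitude": 0.05,
         "onset_s": 0.2, "rise_s": 0.15, "decay_s": 0.8, "event_name": "whisker"},
    ])
    # stimuli are asynchronous to the camera clock; mid-frame is the
    # generic phase (a boundary-aligned event is the degenerate case)
    event_times_s: tuple[float, ...] = (5.05, 15.05, 25.05, 35.05, 45.05)
    event_duration_s: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0


def make_evoked_recording(spec: EvokedSpec = EvokedSpec()
                          ) -> tuple[ImageStack, EventTable, dict]:
    """Evoked recording plus events plus analytic response truth.

    Truth is given per response blob for an event-triggered average aligned
    to the onsets: spatial amplitude map, continuous-time peak latency
    (``onset_s + rise*ln(1+decay/rise)``), the exact post-window AUC, and
    the noise-free onset-crossing frame for threshold
    ``k * noise_sigma`` (NaN threshold truth when noise_sigma == 0).
    """
    rng = np.random.default_rng(spec.seed)
    T, H, W = spec.n_frames, spec.height, spec.width
    t = np.arange(T) / spec.frame_rate_hz
    data = np.zeros((T, H, W))
    rr, cc = np.mgrid[0:H, 0:W]

    rows = []
    names = sorted({r.get("event_name", "stim") for r in spec.responses})
    name_ids = {n: i + 1 for i, n in enumerate(names)}
    for ts in spec.event_times_s:
        for name in names:
            rows.append((ts, "onset", name_ids[name], name))
            rows.append((ts + spec.event_duration_s, "offset", name_ids[name], name))
    events = EventTable.from_rows(rows)

    truth_responses = []
    for resp in spec.responses:
        r0, c0 = resp["center"]
        blob = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * resp["sigma_px"] ** 2))
        amp_map = resp["amplitude"] * blob
        for ts in spec.event_times_s:
            kern = response_kernel(t - ts - resp["onset_s"],
                                   resp["rise_s"], resp["decay_s"])
            data += kern[:, None, None] * amp_map[None]
        t_peak = kernel_peak_time(resp["rise_s"], resp["decay_s"])
        truth_responses.append({
            "event_name": resp.get("event_name", "stim"),
            "amplitude_map": amp_map,
            "onset_s": resp["onset_s"],
            "rise_s": resp["rise_s"],
            "decay_s": resp["decay_s"],
            "peak_latency_s": resp["onset_s"] + t_peak,
        })
    if spec.noise_sigma > 0:
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)

    stack = ImageStack(data, _meta(spec, "fluo"))
    truth = {
        "responses": truth_responses,
        "noise_sigma": spec.noise_sigma,
        "frame_rate_hz": spec.frame_rate_hz,
    }
    return stack, events, truth


def evoked_truth_metrics(spec: EvokedSpec, resp_index: int,
                         pre_s: float, post_s: float, k: float = 2.0
                         ) -> dict:
    """Analytic truth for :func:`mesopipe.events_analysis.compute_metrics`
    run on the event-triggered average of one response blob.

    ``peak_amplitude``: the amplitude map evaluated on the post-window frame
    grid (max of the sampled kernel); ``peak_latency_s``: continuous-time;
    ``auc``: exact kernel integral over the post window; ``onset_latency_s``:
    first frame grid point where the noise-free signal reaches
    ``k * noise_sigma`` (NaN where the blob never crosses).
    """
    from .core_io import frame_of_time

    resp = spec.responses[resp_index]
    rate = spec.frame_rate_hz
    pre_f = int(round(pre_s * rate))
    post_f = int(round(post_s * rate))
    # physical time of post-window frame i after the event: the first
    # at-or-after frame sits delta = f0/rate - ts after it (all default
    # events share the same phase relative to the frame clock)
    ts0 = spec.event_times_s[0]
    delta = frame_of_time(ts0, rate) / rate - ts0
    rel_t = delta + np.arange(post_f) / rate
    kern = response_kernel(rel_t - resp["onset_s"], resp["rise_s"], resp["decay_s"])
    H, W = spec.height, spec.width
    rr, cc = np.mgrid[0:H, 0:W]
    r0, c0 = resp["center"]
    blob = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * resp["sigma_px"] ** 2))
    amp_map = resp["amplitude"] * blob

    peak_amplitude = amp_map * kern.max()
    peak_latency_s = resp["onset_s"] + kernel_peak_time(resp["rise_s"], resp["decay_s"])

    # trapezoid in compute_metrics spans the sampled post frames, i.e.
    # [delta, delta + (post_f - 1)/rate] after the event
    window_s = delta + (post_f - 1) / rate
    active = max(0.0, window_s - resp["onset_s"])
    t_pk = kernel_peak_time(resp["rise_s"], resp["decay_s"])
    norm = (1 - math.exp(-t_pk / resp["rise_s"])) * math.exp(-t_pk / resp["decay_s"])
    auc = amp_map * (_kernel_integral(resp["rise_s"], resp["decay_s"], active) / norm)

    if spec.noise_sigma > 0:
        thr = k * spec.noise_sigma
        signal = amp_map[None] * kern[:, None, None]
        above = signal > thr
        crossed = above.any(axis=0)
        first = above.argmax(axis=0)
        onset_latency_s = np.where(crossed, (first + 1) / rate, np.nan)
    else:
        onset_latency_s = np.full((H, W), np.nan)

    return {
        "peak_amplitude": peak_amplitude,
        "peak_latency_s": peak_latency_s,
        "auc": auc,
        "onset_latency_s": onset_latency_s,
        "amplitude_map": amp_map,
    }


# ---------------------------------------------------------------------------
# connectivity with latent factor
# ---------------------------------------------------------------------------

@dataclass
class ConnectivitySpec:
    """Conditions for the latent-factor connectivity generator.

    Each region's trace is ``loading * z(t) + n_i(t)`` with a shared latent
    ``z ~ N(0, latent_sigma^2)`` and independent region noise
    ``n_i ~ N(0, noise_sigma_i^2)``; every pixel of a region carries the
    region trace plus small independent pixel noise.  The theoretical
    correlation between regions i and j is
    ``l_i l_j s_z^2 / sqrt((l_i^2 s_z^2 + s_i^2)(l_j^2 s_z^2 + s_j^2))``.
    """

    frame_rate_hz: float = 10.0
    n_frames: int = 2000
    height: int = 64
    width: int = 64
    n_regions: int = 4
    loadings: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4)
    latent_sigma: float = 0.03
    noise_sigmas: tuple[float, ...] = (0.01, 0.01, 0.015, 0.01)
    pixel_noise_sigma: float = 0.002
    seed: int = 0

    def region_masks(self) -> list[np.ndarray]:
        """Square blocks tiling the frame left to right, top to bottom."""
        per_row = int(math.ceil(math.sqrt(self.n_regions)))
        bh, bw = self.height // per_row, self.width // per_row
        masks = []
        for i in range(self.n_regions):
            r, c = divmod(i, per_row)
            m = np.zeros((self.height, self.width), dtype=bool)
            m[r * bh + 1:(r + 1) * bh - 1, c * bw + 1:(c + 1) * bw - 1] = True
            masks.append(m)
        return masks

    def theoretical_r(self) -> np.ndarray:
        l = np.asarray(self.loadings[: self.n_regions])
        s2 = np.asarray(self.noise_sigmas[: self.n_regions]) ** 2
        var = l ** 2 * self.latent_sigma ** 2 + s2
        cov = np.outer(l, l) * self.latent_sigma ** 2
        r = cov / np.sqrt(np.outer(var, var))
        np.fill_diagonal(r, 1.0)
        return r


def make_connected_recording(spec: ConnectivitySpec = ConnectivitySpec()
                             ) -> tuple[ImageStack, dict]:
    """Recording whose regions share a latent factor, plus closed-form truth.

    Truth holds the theoretical correlation matrix, the region masks and the
    generated region traces.
    """
    if not (len(spec.loadings) >= spec.n_regions
            and len(spec.noise_sigmas) >= spec.n_regions):
        raise ValueError("need one loading and noise sigma per region")
    rng = np.random.default_rng(spec.seed)
    T, H, W = spec.n_frames, spec.height, spec.width
    z = rng.normal(0.0, spec.latent_sigma, size=T)
    masks = spec.region_masks()
    data = rng.normal(0.0, spec.pixel_noise_sigma, size=(T, H, W))
    region_traces = np.empty((T, spec.n_regions))
    for i, mask in enumerate(masks):
        trace = spec.loadings[i] * z + rng.normal(0.0, spec.noise_sigmas[i], size=T)
        region_traces[:, i] = trace
        data[:, mask] += trace[:, None]
    stack = ImageStack(data, _meta(spec, "fluo"))
    truth = {
        "r": spec.theoretical_r(),
        "region_masks": masks,
        "region_traces": region_traces,
        "latent": z,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# vessel images for registration
# ---------------------------------------------------------------------------

@dataclass
class VesselSpec:
    """Vessel-like reference image: dark smoothed random-walk curves on a
    bright background, mimicking the surface vasculature used as landmarks."""

    height: int = 96
    width: int = 96
    n_vessels: int = 8
    walk_steps: int = 220
    smooth_sigma: float = 1.2
    seed: int = 0


def make_vessel_frame(spec: VesselSpec = VesselSpec()) -> np.ndarray:
    """A single synthetic vessel image in [0, 1] (bright tissue, dark vessels)."""
    from scipy import ndimage

    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    canvas = np.zeros((H, W))
    for _ in range(spec.n_vessels):
        r = rng.uniform(0.15 * H, 0.85 * H)
        c = rng.uniform(0.15 * W, 0.85 * W)
        heading = rng.uniform(0, 2 * math.pi)
        for _ in range(spec.walk_steps):
            heading += rng.normal(0.0, 0.25)
            r += math.sin(heading)
            c += math.cos(heading)
            if not (1 <= r < H - 1 and 1 <= c < W - 1):
                break
            canvas[int(r), int(c)] = 1.0
    canvas = ndimage.gaussian_filter(canvas, spec.smooth_sigma)
    if canvas.max() > 0:
        canvas = canvas / canvas.max()
    background = 0.9 + 0.05 * ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=(H, W)), 6.0)
    return np.clip(background - 0.7 * canvas, 0.0, 1.0)


def make_vessel_pair(spec: VesselSpec, transform: SimilarityTransform
                     ) -> tuple[np.ndarray, np.ndarray]:
    """``(reference, moved)`` where ``moved = apply_transform(reference,
    transform, bilinear)`` — out-of-bounds pixels NaN."""
    reference = make_vessel_frame(spec)
    moved = apply_transform(reference, transform, "bilinear")
    return reference, moved
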