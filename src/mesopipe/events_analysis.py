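"""Event-triggered responses: trial splitting, averaging and response metrics.

A recording is cut into trials around stimulus onsets (block averaging),
trials are grouped and averaged, and per-pixel metrics are read off the
average movie: peak amplitude and latency, onset latency (first crossing of
baseline mean + k standard deviations of the pre-event signal) and the area
under the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import EventTable, ImageStack, frame_of_time

__all__ = [
    "TrialTensor",
    "ResponseMetrics",
    "split_by_events",
    "average_trials",
    "compute_metrics",
    "subtraction_map",
]


@dataclass
class TrialTensor:
    """Event-aligned trials: ``(trial, time, row, col)``.

    The time axis has ``pre_frames + post_frames`` samples; frame
    ``pre_frames`` is the first post-event frame.  Trials whose window would
    run past either end of the recording are dropped, not padded;
    ``n_dropped`` reports how many.
    """

    data: np.ndarray
    pre_frames: int
    post_frames: int
    frame_rate_hz: float
    event_names: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("trial tensor must be 4-D (trial, time, row, col)")
        if self.data.shape[1] != self.pre_frames + self.post_frames:
            raise ValueError("time axis must equal pre_frames + post_frames")
        if len(self.event_names) != self.data.shape[0]:
            raise ValueError("need one event name per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def split_by_events(stack: ImageStack, events: EventTable,
                    pre_s: float, post_s: float,
                    names: list[str] | None = None,
                    baseline_subtract: bool = False) -> TrialTensor:
    """Cut one trial per onset event: ``pre_s`` seconds before to ``post_s``
    after.  ``names`` filters events; ``baseline_subtract`` removes each
    trial's pre-window mean (per pixel)."""
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be nonnegative")
    rate = stack.frame_rate_hz
    pre_frames = frame_of_time(pre_s, rate)
    post_frames = frame_of_time(post_s, rate)
    onsets = events.onsets(names)
    if len(onsets) == 0:
        raise ValueError(
            f"no onset events match names={names!r} "
            f"(available: {events.names})"
        )
    T = stack.shape[0]
    trials, kept_names, dropped = [], [], 0
    for ts, name in zip(onsets["timestamp_s"], onsets["event_name"]):
        f0 = frame_of_time(ts, rate)
        lo, hi = f0 - pre_frames, f0 + post_frames
        if lo < 0 or hi > T:
            dropped += 1
            continue
        seg = stack.data[lo:hi].astype(np.float64)
        if baseline_subtract and pre_frames > 0:
            seg = seg - seg[:pre_frames].mean(axis=0)
        trials.append(seg)
        kept_names.append(name)
    if not trials:
        raise ValueError("every event window exceeds the recording bounds")
    return TrialTensor(
        data=np.stack(trials),
        pre_frames=pre_frames,
        post_frames=post_frames,
        frame_rate_hz=rate,
        event_names=kept_names,
        n_dropped=dropped,
    )


def average_trials(trials: TrialTensor, group_by: str = "all"
                   ) -> dict[str, dict]:
    """Average trials, grouped either into a single ``"all"`` entry or by
    event name.  Each entry carries the mean movie, across-trial SD and SEM
    (both n-1 denominator; NaN for single-trial groups) and the trial count.
    """
    if group_by == "all":
        groups = {"all": np.arange(trials.n_trials)}
    elif group_by == "event_name":
        groups = {}
        for i, name in enumerate(trials.event_names):
            groups.setdefault(name, []).append(i)
        groups = {k: np.asarray(v) for k, v in groups.items()}
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    out = {}
    for name, idx in sorted(groups.items()):
        if len(idx) == 0:
            raise ValueError(f"empty trial group {name!r}")
        block = trials.data[idx]
        mean = block.mean(axis=0)
        if len(idx) > 1:
            sd = block.std(axis=0, ddof=1)
            sem = sd / np.sqrt(len(idx))
        else:
            sd = np.full(mean.shape, np.nan)
            sem = np.full(mean.shape, np.nan)
        out[name] = {"mean": mean, "sd": sd, "sem": sem, "n_trials": int(len(idx))}
    return out


@dataclass
class ResponseMetrics:
    """Per-pixel response metrics of an event-triggered average movie.

    All maps have the frame shape.  ``peak_amplitude`` is baseline-subtracted
    by default (dF/F units); latencies are seconds after the event, with the
    first post-event frame at ``1/frame_rate_hz``; ``onset_latency_s`` is NaN
    where the threshold is never crossed; ``auc`` integrates the
    baseline-subtracted signal over the post window (dF/F * s).
    """

    peak_amplitude: np.ndarray
    peak_latency_s: np.ndarray
    onset_latency_s: np.ndarray
    auc: np.ndarray
    threshold_multiple: float = 2.0

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "peak_amplitude": self.peak_amplitude,
            "peak_latency_s": self.peak_latency_s,
            "onset_latency_s": self.onset_latency_s,
            "auc": self.auc,
        }


def compute_metrics(avg_movie: np.ndarray, pre_frames: int,
                    frame_rate_hz: float, k: float = 2.0,
                    absolute_peak: bool = False) -> ResponseMetrics:
    """Extract per-pixel response metrics from an average movie ``(T, H, W)``.

    Baseline = frames ``[0, pre_frames)``.  Per pixel:

    * peak amplitude: max over the post window of the baseline-subtracted
      signal (raw max with ``absolute_peak=True``); earliest frame wins ties;
    * peak latency: ``(argmax - pre_frames + 1) / rate`` seconds;
    * onset latency: first post-window frame strictly above
      ``baseline_mean + k * baseline_SD`` (sample SD, ddof=1); NaN if never;
    * AUC: trapezoidal integral of the baseline-subtracted post window.
    """
    movie = np.asarray(avg_movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("avg_movie must be 3-D (T, H, W)")
    T = movie.shape[0]
    if pre_frames < 2:
        raise ValueError("pre_frames must be >= 2 to estimate baseline SD")
    if pre_frames >= T:
        raise ValueError("post window is empty")
    baseline = movie[:pre_frames]
    post = movie[pre_frames:]
    b_mean = baseline.mean(axis=0)
    b_sd = baseline.std(axis=0, ddof=1)

    rel = post - b_mean
    argmax = rel.argmax(axis=0)                      # earliest max (np.argmax ties)
    peak = (post.max(axis=0) if absolute_peak else rel.max(axis=0))
    peak_latency = (argmax + 1) / frame_rate_hz

    threshold = b_mean + k * b_sd
    above = post > threshold   # strict: a flat trace never "crosses"
    crossed = above.any(axis=0)
    first = above.argmax(axis=0)
    onset_latency = np.where(crossed, (first + 1) / frame_rate_hz, np.nan)

    auc = np.trapezoid(rel, dx=1.0 / frame_rate_hz, axis=0)

    return ResponseMetrics(
        peak_amplitude=peak,
        peak_latency_s=peak_latency,
        onset_latency_s=onset_latency,
        auc=auc,
        threshold_multiple=k,
    )


def subtraction_map(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Elementwise ``a - b`` for comparing a metric map to a reference map.
    NaN (missing) propagates."""
    a, b = np.asarray(map_a, dtype=float), np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b
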