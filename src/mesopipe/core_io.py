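"""File model for widefield imaging projects.

A recording channel is stored as a headerless ``float32`` little-endian
binary file (``<name>.bin``, C-order, time-major) next to a JSON sidecar
(``<name>.json``) holding the acquisition metadata.  Interleaved-illumination
recordings therefore occupy one file pair per channel (fluorescence, red,
green, ...).  Stimulus/behaviour events travel as a 4-column CSV, regions of
interest as JSON (see :mod:`mesopipe.roi_manager`), and a project — subjects,
groups, acquisitions — as a pretty-printed ``project.json`` manifest.

Conventions used throughout the package:

* arrays are ordered ``time x row x column``, indices are 0-based;
* frame ``t`` starts at ``t / frame_rate_hz`` seconds;
* the first frame at-or-after a timestamp ``ts`` is ``ceil(ts * rate)``,
  with a timestamp landing exactly on a frame boundary assigned to that
  (later) frame;
* missing pixels are NaN and are excluded from means and regressions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

FORMAT_VERSION = "1"

__all__ = [
    "FORMAT_VERSION",
    "RecordingMeta",
    "ImageStack",
    "EventTable",
    "ProjectManifest",
    "frame_of_time",
    "write_stack",
    "read_stack",
    "import_tiff",
    "read_events",
    "write_events",
    "scan_project",
    "load_manifest",
    "save_manifest",
]


class StackFormatError(ValueError):
    """Raised when a binary stack and its sidecar disagree or are malformed."""


@dataclass
class RecordingMeta:
    """Acquisition metadata for a single recording channel."""

    frame_rate_hz: float
    height_px: int
    width_px: int
    n_frames: int
    channel_name: str = "fluo"
    exposure_ms: float | None = None
    wavelength_nm: float | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        for name in ("height_px", "width_px", "n_frames"):
            v = getattr(self, name)
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
            setattr(self, name, int(v))
        for name in ("exposure_ms", "wavelength_nm", "pixel_size_um"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive if given, got {v!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_frames, self.height_px, self.width_px)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImageStack:
    """One illumination channel: a ``(T, H, W)`` array plus its metadata.

    ``history`` is the audit trail: each processing stage appends a
    ``{"stage": ..., "params": {...}}`` record, which is persisted in the
    JSON sidecar so any written stack carries its provenance.
    """

    data: np.ndarray
    meta: RecordingMeta
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D (T,H,W); got ndim={self.data.ndim}")
        if self.data.shape != self.meta.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match metadata {self.meta.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def frame_rate_hz(self) -> float:
        return self.meta.frame_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Start time of every frame, in seconds from recording start."""
        return np.arange(self.meta.n_frames) / self.meta.frame_rate_hz

    def with_data(self, data: np.ndarray, stage: str | None = None,
                  params: dict | None = None) -> "ImageStack":
        """Return a copy holding ``data``, optionally recording a pipeline stage."""
        meta = RecordingMeta(**self.meta.to_dict())
        meta.n_frames = int(data.shape[0])
        hist = [dict(h) for h in self.history]
        if stage is not None:
            hist.append({"stage": stage, "params": params or {}})
        return ImageStack(np.asarray(data), meta, hist)

    def __eq__(self, other: object) -> bool:  # used heavily by round-trip tests
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            self.meta == other.meta
            and np.array_equal(self.data, other.data, equal_nan=True)
        )


def frame_of_time(timestamp_s: float, frame_rate_hz: float) -> int:
    """First frame at-or-after ``timestamp_s`` (frame-start convention).

    ``ceil(ts * rate)``; a timestamp falling exactly on a frame boundary maps
    to that frame.  A small snap tolerance absorbs float representation error
    (e.g. ``3.0 * 10`` evaluating to ``30.000000000000004``).
    """
    x = timestamp_s * frame_rate_hz
    nearest = round(x)
    if abs(x - nearest) < 1e-9 * max(1.0, abs(x)):
        return int(nearest)
    return int(math.ceil(x))


# ---------------------------------------------------------------------------
# binary stack + JSON sidecar
# ---------------------------------------------------------------------------

def _paths(basepath: str | Path) -> tuple[Path, Path]:
    base = Path(basepath)
    if base.suffix in (".bin", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".bin"), base.with_suffix(".json")


def write_stack(stack: ImageStack, basepath: str | Path,
                allow_nan: bool = True) -> tuple[Path, Path]:
    """Write ``stack`` as ``<basepath>.bin`` (float32-LE, C-order, time-major)
    plus ``<basepath>.json`` sidecar.  Returns the two paths."""
    data = np.asarray(stack.data)
    if not allow_nan and not np.isfinite(data).all():
        raise ValueError("stack contains non-finite values and allow_nan is False")
    bin_path, json_path = _paths(basepath)
    data.astype("<f4", copy=False).tofile(bin_path)
    sidecar = stack.meta.to_dict()
    sidecar["format_version"] = FORMAT_VERSION
    sidecar["history"] = stack.history
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return bin_path, json_path


def read_stack(basepath: str | Path) -> ImageStack:
    """Read a binary stack written by :func:`write_stack`."""
    bin_path, json_path = _paths(basepath)
    if not bin_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"missing {bin_path} or {json_path}")
    sidecar = json.loads(json_path.read_text())
    version = sidecar.pop("format_version", None)
    if version != FORMAT_VERSION:
        raise StackFormatError(f"unknown format_version {version!r}")
    history = sidecar.pop("history", [])
    required = ("frame_rate_hz", "height_px", "width_px", "n_frames")
    for name in required:
        if name not in sidecar:
            raise StackFormatError(f"sidecar {json_path} missing required field {name!r}")
    meta = RecordingMeta(**{k: v for k, v in sidecar.items()
                            if k in RecordingMeta.__dataclass_fields__})
    raw = np.fromfile(bin_path, dtype="<f4")
    expected = meta.n_frames * meta.height_px * meta.width_px
    if raw.size != expected:
        raise StackFormatError(
            f"{bin_path}: {raw.size} float32 values on disk, sidecar declares {expected}"
        )
    return ImageStack(raw.reshape(meta.shape), meta, history)


def import_tiff(tiff_path: str | Path, meta_json: str | Path) -> ImageStack:
    """Import a multi-page TIFF plus its JSON metadata sidecar.

    Page order becomes time order; the pixel dtype is promoted to float32.
    ``n_frames``/``height_px``/``width_px`` in the sidecar are optional and,
    when present, validated against the TIFF geometry.
    """
    tiff_path, meta_json = Path(tiff_path), Path(meta_json)
    if not meta_json.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_json}")
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise StackFormatError(f"{tiff_path}: expected grayscale pages, got shape {pages.shape}")
    info = json.loads(meta_json.read_text())
    info.pop("format_version", None)
    info.pop("history", None)
    declared = {k: info.get(k) for k in ("n_frames", "height_px", "width_px")}
    for key, axis in (("n_frames", 0), ("height_px", 1), ("width_px", 2)):
        if declared[key] is not None and declared[key] != pages.shape[axis]:
            raise StackFormatError(
                f"{tiff_path}: sidecar {key}={declared[key]} but TIFF has {pages.shape[axis]}"
            )
    info.update(n_frames=pages.shape[0], height_px=pages.shape[1], width_px=pages.shape[2])
    meta = RecordingMeta(**{k: v for k, v in info.items()
                            if k in RecordingMeta.__dataclass_fields__})
    return ImageStack(pages.astype(np.float32), meta)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["timestamp_s", "state", "event_id", "event_name"]


class EventTable:
    """Timestamped onset/offset events, backed by a pandas DataFrame.

    Rows are kept sorted by timestamp.  Within each ``event_id`` every onset
    must precede its matching offset, and the id-to-name mapping must be
    consistent across the table.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        df = df.loc[:, EVENT_COLUMNS].copy()
        df["timestamp_s"] = df["timestamp_s"].astype(float)
        df["event_id"] = df["event_id"].astype(int)
        df["state"] = df["state"].astype(str)
        df["event_name"] = df["event_name"].astype(str)
        df = df.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["timestamp_s"] < 0).any():
            raise ValueError("negative timestamps are not allowed")
        bad_state = set(df["state"]) - {"onset", "offset"}
        if bad_state:
            raise ValueError(f"unknown event states {sorted(bad_state)}")
        names = df.groupby("event_id")["event_name"].nunique()
        if (names > 1).any():
            dup = names[names > 1].index.tolist()
            raise ValueError(f"event_id(s) {dup} mapped to multiple names")
        ids_per_name = df.groupby("event_name")["event_id"].nunique()
        if (ids_per_name > 1).any():
            dup = ids_per_name[ids_per_name > 1].index.tolist()
            raise ValueError(f"event name(s) {dup} mapped to multiple ids")
        for eid, grp in df.groupby("event_id"):
            depth = 0
            for state, ts in zip(grp["state"], grp["timestamp_s"]):
                depth += 1 if state == "onset" else -1
                if depth < 0:
                    raise ValueError(
                        f"event_id {eid}: offset at t={ts} without a preceding onset"
                    )

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[float, str, int, str]]) -> "EventTable":
        return cls(pd.DataFrame(rows, columns=EVENT_COLUMNS))

    def onsets(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        """Onset rows, optionally restricted to the given event names."""
        df = self.df[self.df["state"] == "onset"]
        if names is not None:
            df = df[df["event_name"].isin(set(names))]
        return df.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return sorted(self.df["event_name"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.df.equals(other.df)


def read_events(csv_path: str | Path) -> EventTable:
    df = pd.read_csv(csv_path)
    return EventTable(df)


def write_events(table: EventTable, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    table.df.to_csv(csv_path, index=False)
    return csv_path


# ---------------------------------------------------------------------------
# project manifest
# ---------------------------------------------------------------------------

MANIFEST_VERSION = "1"
CHANNEL_SUFFIXES = (".bin", ".tif", ".tiff")


@dataclass
class ProjectManifest:
    """Index of a longitudinal project: subjects, groups and acquisitions.

    The manifest never deletes information on rescan: acquisitions whose
    folders vanished are flagged ``missing`` rather than dropped, and
    user-entered group labels and attributes survive rescans untouched.
    """

    project_name: str
    raw_root: str
    save_root: str
    subjects: list[dict] = field(default_factory=list)
    acquisitions: list[dict] = field(default_factory=list)

    def subject_ids(self) -> list[str]:
        return [s["subject_id"] for s in self.subjects]

    def to_json(self) -> str:
        obj = {
            "manifest_version": MANIFEST_VERSION,
            "project_name": self.project_name,
            "raw_root": str(self.raw_root),
            "save_root": str(self.save_root),
            "subjects": sorted(self.subjects, key=lambda s: s["subject_id"]),
            "acquisitions": sorted(
                self.acquisitions,
                key=lambda a: (a["subject_id"], a["acquisition_label"]),
            ),
        }
        return json.dumps(obj, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ProjectManifest":
        obj = json.loads(text)
        version = obj.get("manifest_version")
        if version != MANIFEST_VERSION:
            raise StackFormatError(f"unknown manifest_version {version!r}")
        return cls(
            project_name=obj["project_name"],
            raw_root=obj["raw_root"],
            save_root=obj["save_root"],
            subjects=obj.get("subjects", []),
            acquisitions=obj.get("acquisitions", []),
        )


def save_manifest(manifest: ProjectManifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(manifest.to_json())
    return path


def load_manifest(path: str | Path) -> ProjectManifest:
    return ProjectManifest.from_json(Path(path).read_text())


def _scan_channels(acq_dir: Path) -> dict[str, str]:
    """Channel name -> file path (relative to raw_root's parent of acq_dir)."""
    channels = {}
    for f in sorted(acq_dir.iterdir()):
        if f.suffix.lower() in CHANNEL_SUFFIXES and not f.name.startswith("."):
            channels[f.stem] = f.name
    return channels


def scan_project(manifest: ProjectManifest) -> ProjectManifest:
    """Synchronise the manifest with the ``raw_root/subject/acquisition``
    directory layout.

    New subjects and acquisitions are appended; acquisitions whose folder
    disappeared are flagged ``missing: true`` (never removed); everything the
    user entered by hand (group labels, attributes, modality edits) is left
    untouched.  Scanning an unchanged tree is a byte-identical no-op.
    """
    raw_root = Path(manifest.raw_root)
    if not raw_root.is_dir():
        raise FileNotFoundError(f"raw_root {raw_root} does not exist")

    out = ProjectManifest(
        project_name=manifest.project_name,
        raw_root=str(manifest.raw_root),
        save_root=str(manifest.save_root),
        subjects=[dict(s) for s in manifest.subjects],
        acquisitions=[dict(a) for a in manifest.acquisitions],
    )
    known_subjects = {s["subject_id"] for s in out.subjects}
    known_acqs = {(a["subject_id"], a["acquisition_label"]): a for a in out.acquisitions}

    seen: set[tuple[str, str]] = set()
    for subj_dir in sorted(p for p in raw_root.iterdir() if p.is_dir()):
        subject_id = subj_dir.name
        if subject_id not in known_subjects:
            out.subjects.append(
                {"subject_id": subject_id, "group_label": "", "attributes": {}}
            )
            known_subjects.add(subject_id)
        acq_dirs = sorted(p for p in subj_dir.iterdir() if p.is_dir())
        for idx, acq_dir in enumerate(acq_dirs):
            key = (subject_id, acq_dir.name)
            seen.add(key)
            channels = _scan_channels(acq_dir)
            if key in known_acqs:
                entry = known_acqs[key]
                entry["channels"] = channels
                entry["missing"] = False
            else:
                out.acquisitions.append(
                    {
                        "subject_id": subject_id,
                        "acquisition_label": acq_dir.name,
                        "modality": "imaging",
                        "timepoint_index": idx,
                        "channels": channels,
                        "missing": False,
                    }
                )
    for entry in out.acquisitions:
        if (entry["subject_id"], entry["acquisition_label"]) not in seen:
            entry["missing"] = True
    return out
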