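"""Batch execution of preprocessing/analysis stages across a project.

A pipeline config is an ordered list of ``{"stage": name, "params": {...}}``
entries (JSON or YAML).  ``run_pipeline`` applies the stages, in order, to
every non-missing acquisition in a project manifest, writing outputs and an
audit trail under ``save_root/subject/acquisition/``.  Failures are isolated
per acquisition: with ``continue_on_error`` the run completes and reports
which acquisitions failed.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import connectivity, preprocess
from .core_io import ImageStack, ProjectManifest, read_stack, write_stack

__all__ = ["PipelineError", "load_config", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# stage registry: name -> callable(channels: dict[str, ImageStack], params)
# Stack stages replace the channel they operate on; map stages emit a TIFF.
# ---------------------------------------------------------------------------

def _stage_dff(channels, params):
    ch = params.get("channel", "fluo")
    channels[ch] = preprocess.normalize_dff(
        channels[ch],
        baseline=params.get("baseline", "whole_trace"),
        frame_range=tuple(params["frame_range"]) if params.get("frame_range") else None,
    )
    return None


def _stage_temporal_filter(channels, params):
    ch = params.get("channel", "fluo")
    channels[ch] = preprocess.temporal_filter(
        channels[ch], low_hz=params.get("low_hz"), high_hz=params.get("high_hz"),
        order=int(params.get("order", 4)))
    return None


def _stage_gsr(channels, params):
    ch = params.get("channel", "fluo")
    channels[ch] = preprocess.global_signal_regression(
        channels[ch], mode=params.get("mode", "regress"))
    return None


def _stage_hemo_regress(channels, params):
    ch = params.get("channel", "fluo")
    refl_names = params.get("reflectance")
    if refl_names is None:
        refl_names = sorted(n for n in channels if n != ch)
    if not refl_names:
        raise PipelineError("hemo_regress: no reflectance channels present")
    result = preprocess.regress_hemodynamics(
        channels[ch], [channels[n] for n in refl_names])
    channels[ch] = result.corrected
    return None


def _stage_ratiometric(channels, params):
    ch = params.get("channel", "fluo")
    refl = params.get("reflectance", "green")
    channels[ch] = preprocess.ratiometric_correction(channels[ch], channels[refl])
    return None


def _stage_sd_map(channels, params):
    ch = params.get("channel", "fluo")
    return {"sd_map.tif": connectivity.sd_map(channels[ch]).astype(np.float32)}


def _stage_seed_map(channels, params):
    ch = params.get("channel", "fluo")
    seed = tuple(params["seed"])
    r = connectivity.seed_correlation_map(channels[ch], seed)
    return {"seed_map.tif": r.astype(np.float32)}


STAGES = {
    "dff": _stage_dff,
    "temporal_filter": _stage_temporal_filter,
    "global_signal_regression": _stage_gsr,
    "hemo_regress": _stage_hemo_regress,
    "ratiometric": _stage_ratiometric,
    "sd_map": _stage_sd_map,
    "seed_map": _stage_seed_map,
}


def load_config(path: str | Path) -> list[dict]:
    """Load an ordered stage list from a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if isinstance(cfg, dict):
        cfg = cfg.get("stages", [])
    if not isinstance(cfg, list):
        raise PipelineError("pipeline config must be a list of stages")
    for entry in cfg:
        name = entry.get("stage")
        if name not in STAGES:
            raise PipelineError(
                f"unknown stage {name!r}; available: {sorted(STAGES)}")
    return cfg


@dataclass
class RunReport:
    n_total: int = 0
    n_ok: int = 0
    n_skipped: int = 0
    failures: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _config_fingerprint(config: list[dict]) -> str:
    return json.dumps(config, sort_keys=True)


def run_pipeline(config: list[dict], manifest: ProjectManifest,
                 continue_on_error: bool = True,
                 skip_existing: bool = False,
                 log: list[str] | None = None) -> RunReport:
    """Apply the configured stages to every acquisition of the project.

    Outputs land in ``save_root/subject/acquisition/``: processed channels
    as binary stacks, metric maps as 32-bit float TIFFs, plus an
    ``audit.json`` recording stages, parameters, timings and the config
    fingerprint.  ``skip_existing`` skips acquisitions whose audit is newer
    than all their inputs and was produced by an identical config.
    """
    raw_root, save_root = Path(manifest.raw_root), Path(manifest.save_root)
    fingerprint = _config_fingerprint(config)
    report = RunReport()
    for acq in manifest.acquisitions:
        if acq.get("missing"):
            continue
        report.n_total += 1
        acq_raw = raw_root / acq["subject_id"] / acq["acquisition_label"]
        acq_out = save_root / acq["subject_id"] / acq["acquisition_label"]
        audit_path = acq_out / "audit.json"

        in_paths = [acq_raw / fname for fname in acq["channels"].values()]
        if skip_existing and audit_path.exists():
            audit = json.loads(audit_path.read_text())
            newest_input = max((p.stat().st_mtime for p in in_paths), default=0.0)
            if (audit.get("config_fingerprint") == fingerprint
                    and audit_path.stat().st_mtime >= newest_input):
                report.n_skipped += 1
                continue
        try:
            t0 = time.monotonic()
            channels: dict[str, ImageStack] = {}
            for name, fname in acq["channels"].items():
                if fname.endswith(".bin"):
                    channels[name] = read_stack(acq_raw / fname)
            if not channels:
                raise PipelineError("no readable channels")
            acq_out.mkdir(parents=True, exist_ok=True)
            stage_log = []
            for entry in config:
                name, params = entry["stage"], entry.get("params", {})
                if name not in STAGES:
                    raise PipelineError(
                        f"unknown stage {name!r}; available: {sorted(STAGES)}")
                s0 = time.monotonic()
                maps = STAGES[name](channels, params)
                stage_log.append({"stage": name, "params": params,
                                  "seconds": round(time.monotonic() - s0, 4)})
                if maps:
                    for fname, arr in maps.items():
                        tifffile.imwrite(acq_out / fname, arr)
            for name, stack in channels.items():
                write_stack(stack, acq_out / name)
            audit = {
                "config_fingerprint": fingerprint,
                "stages": stage_log,
                "seconds": round(time.monotonic() - t0, 4),
            }
            audit_path.write_text(json.dumps(audit, indent=2, sort_keys=True) + "\n")
            report.n_ok += 1
            if log is not None:
                log.append(f"ok {acq['subject_id']}/{acq['acquisition_label']}"
                           f" ({audit['seconds']}s)")
        except Exception as exc:  # isolate failures per acquisition
            key = f"{acq['subject_id']}/{acq['acquisition_label']}"
            report.failures[key] = f"{type(exc).__name__}: {exc}"
            if log is not None:
                log.append(f"FAIL {key}: {exc}")
            if not continue_on_error:
                raise PipelineError(f"{key} failed: {exc}\n"
                                    + traceback.format_exc()) from exc
    return report
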