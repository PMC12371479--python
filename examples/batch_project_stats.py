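"""Batch-process a longitudinal project and run group statistics.

Builds a small two-group project (control vs treatment, 8 mice, 2 sessions
each) on disk, runs a dF/F + SD-map pipeline over every acquisition, writes
per-ROI metrics, aggregates them into a long table and lets the dispatcher
choose the appropriate statistical test.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import mesopipe as mp
from mesopipe.pipeline import run_pipeline
from mesopipe.stats_groups import aggregate, select_and_run_test

rng = np.random.default_rng(0)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    raw = tmp / "raw"
    for s in range(8):
        for a in range(2):
            d = raw / f"m{s:02d}" / f"ses{a}"
            d.mkdir(parents=True)
            data = rng.normal(1.0, 0.05, (60, 16, 16))
            meta = mp.RecordingMeta(frame_rate_hz=10.0, height_px=16,
                                    width_px=16, n_frames=60)
            mp.write_stack(mp.ImageStack(data, meta), d / "fluo")

    manifest = mp.scan_project(
        mp.ProjectManifest("demo", str(raw), str(tmp / "out")))
    for subj in manifest.subjects:
        idx = int(subj["subject_id"][1:])
        subj["group_label"] = "control" if idx < 4 else "treatment"

    report = run_pipeline([{"stage": "dff", "params": {}},
                           {"stage": "sd_map", "params": {}}], manifest)
    print(f"pipeline: {report.n_ok}/{report.n_total} acquisitions processed, "
          f"{len(report.failures)} failures")

    # per-acquisition ROI metric: mean SD in a central ROI (a treatment
    # effect is injected so the group test has something to find)
    import tifffile
    for acq in manifest.acquisitions:
        out_dir = Path(manifest.save_root) / acq["subject_id"] / acq["acquisition_label"]
        sd = tifffile.imread(out_dir / "sd_map.tif")
        value = float(sd[4:12, 4:12].mean())
        if acq["subject_id"] >= "m04":
            value *= 1.35
        pd.DataFrame({"roi_name": ["center"], "metric_name": ["sd"],
                      "value": [value]}).to_csv(out_dir / "metrics.csv",
                                                index=False)

    table, missing = aggregate(manifest)
    print(f"aggregated {len(table)} rows ({len(missing)} missing)")
    sub = table[table["timepoint_index"] == 0]
    result = select_and_run_test(sub, "two_independent")
    print(f"dispatch chose: {result.test_name}")
    print(f"statistic = {result.statistic:.3f}, p = {result.p_value:.4f}")
    for chk in result.assumption_checks:
        print(f"  {chk.name}: p = {chk.p_value:.3f} "
              f"({'pass' if chk.passed else 'fail'})")
print()
print("With normal per-group samples and homogeneous variances the")
print("dispatcher applies an independent two-sample t-test; a small p-value")
print("reflects the injected 35% increase in signal SD in the treatment group.")
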