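"""Group-level aggregation and automatic statistical test selection.

Per-ROI metrics from many acquisitions are gathered into one long-format
table (subject, group, acquisition, timepoint, modality, ROI, metric,
value), exportable as CSV.  A small dispatcher then picks the test that
matches the design and the data: parametric when the per-group samples look
normal (Shapiro-Wilk) and — for ANOVA and the independent t-test — the
variances homogeneous (median-centered Levene), nonparametric otherwise.

Designs
-------
``two_independent``   control vs. treatment, one value per subject
``paired_pre_post``   one group measured before and after a manipulation
``multi_group_oneway``  three or more independent groups
``group_by_time``     group x timepoint (two-way ANOVA when assumptions
                      hold; otherwise per-timepoint two-group dispatch with
                      Holm correction)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ProjectManifest

__all__ = [
    "GROUP_TABLE_COLUMNS",
    "AssumptionCheck",
    "StatResult",
    "aggregate",
    "select_and_run_test",
    "holm_correction",
]

GROUP_TABLE_COLUMNS = [
    "subject_id", "group_label", "acquisition_label", "timepoint_index",
    "modality", "roi_name", "metric_name", "value",
]

ALPHA_ASSUMPTION = 0.05


def aggregate(manifest: ProjectManifest, metrics_filename: str = "metrics.csv"
              ) -> tuple[pd.DataFrame, list[str]]:
    """Collect per-acquisition ROI metrics into one long-format table.

    Each acquisition is expected to have a ``metrics_filename`` CSV
    (``roi_name,metric_name,value``) under
    ``save_root/subject/acquisition/``.  Returns ``(table, missing)`` where
    ``missing`` lists acquisitions without a metrics file — reported, never
    silently dropped.  Row order is deterministic (sorted on all keys) so
    re-aggregation is byte-identical.
    """
    save_root = Path(manifest.save_root)
    groups = {s["subject_id"]: s.get("group_label", "") for s in manifest.subjects}
    rows, missing = [], []
    for acq in sorted(manifest.acquisitions,
                      key=lambda a: (a["subject_id"], a["acquisition_label"])):
        path = save_root / acq["subject_id"] / acq["acquisition_label"] / metrics_filename
        if not path.exists():
            missing.append(f"{acq['subject_id']}/{acq['acquisition_label']}")
            continue
        df = pd.read_csv(path)
        for _, r in df.iterrows():
            rows.append({
                "subject_id": acq["subject_id"],
                "group_label": groups.get(acq["subject_id"], ""),
                "acquisition_label": acq["acquisition_label"],
                "timepoint_index": acq.get("timepoint_index", 0),
                "modality": acq.get("modality", "imaging"),
                "roi_name": r["roi_name"],
                "metric_name": r["metric_name"],
                "value": float(r["value"]),
            })
    table = pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)
    table = table.sort_values(GROUP_TABLE_COLUMNS[:-1], kind="stable").reset_index(drop=True)
    return table, missing


@dataclass
class AssumptionCheck:
    name: str
    statistic: float
    p_value: float
    passed: bool


@dataclass
class StatResult:
    """Outcome of the automatic test dispatch."""

    design: str
    test_name: str
    statistic: float
    p_value: float
    assumption_checks: list[AssumptionCheck] = field(default_factory=list)
    per_timepoint: list["StatResult"] | None = None
    extras: dict = field(default_factory=dict)


def holm_correction(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone in raw-p rank order)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _shapiro(sample: np.ndarray, label: str) -> AssumptionCheck:
    if len(sample) < 3:
        warnings.warn(
            f"{label}: n={len(sample)} < 3, cannot test normality; "
            "falling back to nonparametric", RuntimeWarning)
        return AssumptionCheck(f"shapiro_{label}", np.nan, 0.0, False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.shapiro(sample)
    return AssumptionCheck(f"shapiro_{label}", float(stat), float(p),
                           p > ALPHA_ASSUMPTION)


def _levene(groups: list[np.ndarray]) -> AssumptionCheck:
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.levene(*groups, center="median")
    # degenerate (identical/zero-spread) groups give nan -> treat as a pass:
    # there is no evidence of heteroscedasticity
    passed = bool(p > ALPHA_ASSUMPTION) if np.isfinite(p) else True
    return AssumptionCheck("levene", float(stat), float(p), passed)


def _two_independent(a: np.ndarray, b: np.ndarray, alpha: float) -> StatResult:
    checks = [_shapiro(a, "group1"), _shapiro(b, "group2")]
    normal = checks[0].passed and checks[1].passed
    lev = _levene([a, b])
    checks.append(lev)
    if normal:
        stat, p = stats.ttest_ind(a, b, equal_var=lev.passed)
        name = "t-test, independent" if lev.passed else "t-test, independent (Welch)"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
    return StatResult("two_independent", name, float(stat), float(p), checks)


def _paired(a: np.ndarray, b: np.ndarray, alpha: float) -> StatResult:
    if len(a) != len(b):
        raise ValueError("paired design needs equal-length pre/post samples")
    diff = a - b
    checks = [_shapiro(diff, "differences")]
    if checks[0].passed:
        stat, p = stats.ttest_rel(a, b)
        name = "t-test, paired"
    else:
        stat, p = stats.wilcoxon(a, b)
        name = "Wilcoxon signed-rank"
    return StatResult("paired_pre_post", name, float(stat), float(p), checks)


def _oneway(groups: list[np.ndarray], alpha: float) -> StatResult:
    checks = [_shapiro(g, f"group{i + 1}") for i, g in enumerate(groups)]
    lev = _levene(groups)
    checks.append(lev)
    if all(c.passed for c in checks):
        stat, p = stats.f_oneway(*groups)
        name = "one-way ANOVA"
    else:
        stat, p = stats.kruskal(*groups)
        name = "Kruskal-Wallis"
    return StatResult("multi_group_oneway", name, float(stat), float(p), checks)


def _group_by_time(table: pd.DataFrame, alpha: float) -> StatResult:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    cells = {k: g["value"].to_numpy(dtype=float)
             for k, g in table.groupby(["group_label", "timepoint_index"])}
    checks = [_shapiro(v, f"{g}_t{t}") for (g, t), v in sorted(cells.items())]
    lev = _levene(list(cells.values()))
    checks.append(lev)
    if all(c.passed for c in checks):
        df = table.rename(columns={"group_label": "group",
                                   "timepoint_index": "time"}).copy()
        df["time"] = df["time"].astype(str)
        model = ols("value ~ C(group) * C(time)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        inter = "C(group):C(time)"
        return StatResult(
            "group_by_time", "two-way ANOVA (group x time)",
            float(anova.loc[inter, "F"]), float(anova.loc[inter, "PR(>F)"]),
            checks,
            extras={"anova_table": anova.to_dict(),
                    "group_p": float(anova.loc["C(group)", "PR(>F)"]),
                    "time_p": float(anova.loc["C(time)", "PR(>F)"])},
        )
    # nonparametric fallback: per-timepoint two-group dispatch, Holm-corrected
    groups = sorted(table["group_label"].unique())
    if len(groups) != 2:
        raise ValueError("nonparametric group_by_time fallback needs exactly 2 groups")
    per_tp = []
    for tp in sorted(table["timepoint_index"].unique()):
        sub = table[table["timepoint_index"] == tp]
        a = sub[sub["group_label"] == groups[0]]["value"].to_numpy(dtype=float)
        b = sub[sub["group_label"] == groups[1]]["value"].to_numpy(dtype=float)
        per_tp.append(_two_independent(a, b, alpha))
    adj = holm_correction([r.p_value for r in per_tp])
    for r, p_adj in zip(per_tp, adj):
        r.extras["p_holm"] = float(p_adj)
    best = int(np.argmin(adj))
    return StatResult(
        "group_by_time", "per-timepoint dispatch + Holm",
        per_tp[best].statistic, float(adj[best]),
        checks, per_timepoint=per_tp,
    )


def select_and_run_test(table: pd.DataFrame, design: str,
                        alpha: float = 0.05) -> StatResult:
    """Dispatch to the test matching ``design`` and the data's distribution.

    ``table`` is a long-format group table (only ``group_label``,
    ``timepoint_index`` and ``value`` are consulted; filter to one ROI and
    metric first).  Normality is judged by Shapiro-Wilk per group (per cell
    for ``group_by_time``; on the differences for ``paired_pre_post``) and
    homoscedasticity by median-centered Levene; failing either sends the
    data to the nonparametric branch.
    """
    if "value" not in table.columns:
        raise ValueError("table must have a 'value' column")
    values = table["value"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")

    if design == "two_independent":
        groups = [g["value"].to_numpy(dtype=float)
                  for _, g in table.groupby("group_label")]
        if len(groups) != 2:
            raise ValueError(f"two_independent needs 2 groups, found {len(groups)}")
        return _two_independent(groups[0], groups[1], alpha)
    if design == "paired_pre_post":
        tps = sorted(table["timepoint_index"].unique())
        if len(tps) != 2:
            raise ValueError("paired_pre_post needs exactly 2 timepoints")
        pre = table[table["timepoint_index"] == tps[0]].sort_values("subject_id")
        post = table[table["timepoint_index"] == tps[1]].sort_values("subject_id")
        if list(pre["subject_id"]) != list(post["subject_id"]):
            raise ValueError("pre/post subject sets differ")
        return _paired(pre["value"].to_numpy(dtype=float),
                       post["value"].to_numpy(dtype=float), alpha)
    if design == "multi_group_oneway":
        groups = [g["value"].to_numpy(dtype=float)
                  for _, g in table.groupby("group_label")]
        if len(groups) < 3:
            raise ValueError("multi_group_oneway needs >= 3 groups")
        return _oneway(groups, alpha)
    if design == "group_by_time":
        return _group_by_time(table, alpha)
    raise ValueError(f"unknown design {design!r}")
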