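"""Cohort statistics and report tables.

Two-sided tests at alpha = 0.05: Shapiro-Wilk for normality, mean-centred
Levene for variance homogeneity, paired t for left-vs-right loaded forces
and pre-vs-post rotation.  When homogeneity fails for an independent-sample
comparison, Welch's correction is applied (and noted in the output).
Summaries render mean +/- SD rows as CSV and Markdown; p-values display
with three decimals and a "0.000" floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatsError

__all__ = [
    "CohortSummary",
    "normality_check",
    "variance_homogeneity",
    "paired_t",
    "welch_t",
    "summarize_cohort",
    "format_p",
]

ALPHA = 0.05

#: metric key -> (left attribute description) used by summarize_cohort
_METRIC_FIELDS = (
    "trigger_loaded_max",
    "stretch_loaded_max",
    "trigger_time",
    "extension_amplitude",
    "max_rotation_pre",
    "max_rotation_post",
)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a sample of size 3..50."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 50:
        raise StatsError(f"Shapiro-Wilk requires 3 <= n <= 50, got n={len(x)}")
    if np.ptp(x) == 0:
        raise StatsError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def variance_homogeneity(a, b) -> tuple[float, float]:
    """Mean-centred Levene statistic and p for two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("Levene test requires n >= 2 per group")
    res = stats.levene(a, b, center="mean")
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y) -> tuple[float, float, float]:
    """Two-sided paired t: (t, p, mean difference x - y), df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError(f"paired samples must have equal length ({len(x)} vs {len(y)})")
    if len(x) < 2:
        raise StatsError("paired t requires n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise StatsError("paired t undefined: differences have zero variance")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), float(np.mean(d))


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t for independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("Welch t requires n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def format_p(p: float) -> str:
    """Three-decimal p with a 0.000 display floor."""
    return f"{max(p, 0.0):.3f}"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Descriptives, comparisons and assumption checks for one cohort."""

    descriptives: pd.DataFrame       # metric, side, n, mean, sd, min, max
    comparisons: pd.DataFrame        # comparison, test, t, p, mean_diff, n
    assumption_checks: pd.DataFrame  # metric, shapiro_W, shapiro_p, levene ...
    dropped_pairs: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        lines = ["# Cohort summary", "", "## Descriptives (mean ± SD)", ""]
        lines.append("| Metric | Side | n | mean ± SD | min | max |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in self.descriptives.iterrows():
            lines.append(
                f"| {r['metric']} | {r['side']} | {int(r['n'])} | "
                f"{r['mean']:.2f} ± {r['sd']:.2f} | {r['min']:.2f} | {r['max']:.2f} |"
            )
        lines += ["", "## Comparisons", "", "| Comparison | Test | t | p | n |", "|---|---|---|---|---|"]
        for _, r in self.comparisons.iterrows():
            lines.append(
                f"| {r['comparison']} | {r['test']} | {r['t']:.3f} | {format_p(r['p'])} | {int(r['n'])} |"
            )
        return "\n".join(lines) + "\n"


def _metrics_frame(metrics: list) -> pd.DataFrame:
    rows = []
    for i, rec in enumerate(metrics):
        if isinstance(rec, dict):
            for side, m in rec.items():
                rows.append({"subject": i, **m.to_dict()})
        else:
            rows.append({"subject": i, **rec.to_dict()})
    return pd.DataFrame(rows)


def summarize_cohort(metrics: list) -> CohortSummary:
    """Cohort tables from per-trial metrics.

    ``metrics`` is a list of per-subject ``{side: ManipulationMetrics}``
    dicts (or flat ManipulationMetrics records).  Left-vs-right loaded-force
    comparisons use the paired t over subjects with both sides; pre-vs-post
    rotation uses the left side.  Subjects with a missing member of a pair
    are dropped pairwise, with counts recorded.
    """
    df = _metrics_frame(metrics)
    if df["subject"].nunique() < 2:
        raise StatsError("cohort summary requires >= 2 subjects")

    col_of = {
        "trigger_loaded_max": "trigger_loaded_max_N",
        "stretch_loaded_max": "stretch_loaded_max_N",
        "trigger_time": "trigger_time_s",
        "extension_amplitude": "extension_amplitude_mm",
        "max_rotation_pre": "max_rotation_pre_deg",
        "max_rotation_post": "max_rotation_post_deg",
    }

    desc_rows = []
    for metric in _METRIC_FIELDS:
        col = col_of[metric]
        for side, grp in df.groupby("side"):
            vals = grp[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            desc_rows.append(
                {
                    "metric": metric,
                    "side": side,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "min": float(np.min(vals)),
                    "max": float(np.max(vals)),
                }
            )
    descriptives = pd.DataFrame(desc_rows)

    comp_rows = []
    check_rows = []
    dropped: dict = {}

    wide = df.pivot_table(index="subject", columns="side", aggfunc="first")

    def _paired(metric_col, col_a, col_b, label):
        if (metric_col, col_a) not in wide.columns or (metric_col, col_b) not in wide.columns:
            return
        sub = wide[[(metric_col, col_a), (metric_col, col_b)]].dropna()
        dropped[label] = int(len(wide) - len(sub))
        if len(sub) < 2:
            return
        a = sub[(metric_col, col_a)].to_numpy(dtype=float)
        b = sub[(metric_col, col_b)].to_numpy(dtype=float)
        try:
            for name, vals in ((col_a, a), (col_b, b)):
                w, p = normality_check(vals)
                check_rows.append(
                    {"comparison": label, "group": name, "check": "shapiro", "stat": w, "p": p}
                )
            lv, lp = variance_homogeneity(a, b)
            check_rows.append(
                {"comparison": label, "group": "both", "check": "levene", "stat": lv, "p": lp}
            )
        except StatsError:
            pass
        t, p, md = paired_t(a, b)
        comp_rows.append(
            {"comparison": label, "test": "paired_t", "t": t, "p": p, "mean_diff": md, "n": len(sub)}
        )

    _paired("trigger_loaded_max_N", "left_rotation", "right_rotation", "trigger loaded force: left vs right")
    _paired("stretch_loaded_max_N", "left_rotation", "right_rotation", "stretch loaded force: left vs right")

    # pre vs post rotation, left side
    if "side" in df.columns:
        left = df[df["side"] == "left_rotation"].set_index("subject")
        pre = left["max_rotation_pre_deg"]
        post = left["max_rotation_post_deg"]
        both = pd.concat([pre, post], axis=1).dropna()
        dropped["rotation: pre vs post"] = int(len(left) - len(both))
        if len(both) >= 2:
            a = both["max_rotation_pre_deg"].to_numpy(dtype=float)
            b = both["max_rotation_post_deg"].to_numpy(dtype=float)
            try:
                t, p, md = paired_t(a, b)
                comp_rows.append(
                    {
                        "comparison": "rotation: pre vs post",
                        "test": "paired_t",
                        "t": t,
                        "p": p,
                        "mean_diff": md,
                        "n": len(both),
                    }
                )
            except StatsError:
                pass

    return CohortSummary(
        descriptives=descriptives,
        comparisons=pd.DataFrame(comp_rows, columns=["comparison", "test", "t", "p", "mean_diff", "n"]),
        assumption_checks=pd.DataFrame(check_rows, columns=["comparison", "group", "check", "stat", "p"]),
        dropped_pairs=dropped,
    )
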