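"""Study-style output tables and the slot-profile figure.

Layouts mirror the usual reporting of workplace-activity interventions:
a baseline table (group means +/- SD with a between-group p per variable),
a change table (pre/post cell means +/- SD with time-effect, interaction and
post hoc p columns), a per-space utilization table (mean +/- SE of counts
per 15 min), and a per-zone slot-profile plot for the shared workstations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .anova import AnovaResult, baseline_tests

__all__ = [
    "METRIC_LABELS",
    "render_table1",
    "render_table2",
    "render_table3",
    "plot_slot_profiles",
]

#: Reported metrics: column name in the phase summary -> printed row label.
METRIC_LABELS = {
    "wear_min_working": "Wearing time, min/working hours",
    "sb_min_norm": "SB time, min/working hours",
    "prolonged_sb_min_norm": "Prolonged SB time, min/working hours",
    "total_pa_min_norm": "Total PA, min/working hours",
    "lpa_min_norm": "Light-intensity PA, min/working hours",
    "mvpa_min_norm": "Moderate- to vigorous-intensity PA, min/working hours",
    "wear_min_allday": "Wearing time, min/day",
    "sb_min_allday": "SB time, min/day",
    "prolonged_sb_min_allday": "Prolonged SB time, min/day",
    "total_pa_min_allday": "Total PA, min/day",
    "lpa_min_allday": "Light-intensity PA, min/day",
    "mvpa_min_allday": "Moderate- to vigorous-intensity PA, min/day",
}


def render_table1(phase_pre: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Baseline table: per-metric group means +/- SD and the independent
    t-test p, from the pre-phase summaries."""
    metrics = metrics or [m for m in METRIC_LABELS if m in phase_pre.columns]
    rows = []
    groups = sorted(phase_pre["group"].unique())
    for metric in metrics:
        row: dict[str, object] = {"variable": METRIC_LABELS.get(metric, metric)}
        for g in groups:
            vals = phase_pre.loc[phase_pre["group"] == g, metric]
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = vals.std(ddof=1)
        if len(groups) == 2:
            p = baseline_tests(phase_pre, "group", continuous=[metric])["p"].iloc[0]
            row["p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def render_table2(
    phase_df: pd.DataFrame,
    anova_results: dict[str, AnovaResult],
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Change table: pre/post cell means +/- SD per group, with time-effect,
    interaction and Bonferroni post hoc p columns per metric.

    Post hoc cells are left blank (NaN) when the interaction was not
    significant — never rendered as zeros.
    """
    metrics = metrics or list(anova_results)
    rows = []
    for metric in metrics:
        res = anova_results[metric]
        posthoc = res.posthoc if res.posthoc is not None else pd.DataFrame()
        for g in sorted(phase_df["group"].unique()):
            row: dict[str, object] = {
                "variable": METRIC_LABELS.get(metric, metric),
                "group": g,
            }
            for ph in ("pre", "post"):
                vals = phase_df.loc[
                    (phase_df["group"] == g) & (phase_df["phase"] == ph), metric
                ]
                row[f"{ph}_mean"] = vals.mean()
                row[f"{ph}_sd"] = vals.std(ddof=1)
            row["p_time"] = res.p("within")
            row["p_interaction"] = res.p("interaction")
            hit = (
                posthoc[posthoc["between_level"] == g] if len(posthoc) else posthoc
            )
            row["p_posthoc"] = float(hit["p_adj"].iloc[0]) if len(hit) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def render_table3(
    space_summary: pd.DataFrame,
    anova_p: dict[str, dict[str, float | str]] | None = None,
) -> pd.DataFrame:
    """Per-space utilization table: mean +/- SE of detections per 15 min,
    with the space/time/interaction p-values of each analysis block (aisle,
    workstation) when available; 'not applicable' blocks render as text."""
    out = space_summary.copy()
    if anova_p:
        for block, ps in anova_p.items():
            for key, val in ps.items():
                out.loc[out["block"] == block, f"p_{key}"] = val
    return out


def plot_slot_profiles(profile: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Figure-style report: per-slot detection counts per shared workstation,
    one panel per zone, thin lines per day plus the across-day mean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = profile.columns.get_level_values("label").unique()
    fig, axes = plt.subplots(
        len(labels), 1, figsize=(7, 2.2 * len(labels)), sharex=True, squeeze=False
    )
    for ax, label in zip(axes[:, 0], labels):
        sub = profile[label]
        for col in sub.columns:
            if col == "mean":
                ax.plot(sub.index, sub[col], color="k", lw=2, label="mean")
            else:
                ax.plot(sub.index, sub[col], lw=0.8, alpha=0.6, label=f"day {col}")
        ax.set_ylabel("persons / 15 min")
        ax.set_title(label, fontsize=9)
        ax.legend(fontsize=6, ncol=4)
    axes[-1, 0].set_xlabel("slot index (15 min from recording start)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
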