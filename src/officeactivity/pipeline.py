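"""End-to-end orchestration: simulate -> process -> analyze -> report.

A single :class:`PipelineConfig` (YAML-loadable) drives all stages; each
step reads the named artifacts of earlier steps from the output directory
and every file written is recorded, with a SHA-256 hash, in
``manifest.json``. Identical config + seed give identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import pandas as pd
import yaml

from . import io as oio
from .accelerometry import (
    WorkingWindow,
    summarize_days,
    summarize_phase,
)
from .anova import (
    AliasedCovariateError,
    AnovaResult,
    NotApplicableError,
    bonferroni_posthoc,
    mixed_ancova,
    mixed_anova,
)
from .report import (
    METRIC_LABELS,
    plot_slot_profiles,
    render_table1,
    render_table2,
)
from .spaces import (
    AISLE_CATEGORIES,
    OfficePlan,
    aggregate_slot_counts,
    summarize_space,
    slot_profile,
)
from .synthetic import (
    GROUP_BASELINE_MEANS,
    PHASES,
    AccelSimConfig,
    VideoSimConfig,
    default_zone_intensities,
    generate_detection_log,
    generate_entry_exit_log,
    generate_epoch_series,
    generate_office_plan,
)

__all__ = ["PipelineConfig", "run_pipeline", "STEPS"]

log = logging.getLogger("officeactivity")

STEPS = ("simulate", "accel", "video", "anova", "report")

#: Mean daily in-office hours per group x phase, as reported.
DEFAULT_OFFICE_HOURS = {
    ("control", "pre"): 7.2,
    ("control", "post"): 7.7,
    ("renovation", "pre"): 6.2,
    ("renovation", "post"): 7.3,
}


@dataclass
class PipelineConfig:
    """Configuration for the full pipeline (see README for the YAML form)."""

    outdir: str = "results/run"
    seed: int = 0
    accel: AccelSimConfig = field(default_factory=lambda: AccelSimConfig())
    group_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GROUP_BASELINE_MEANS)
    )
    office_hours: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_OFFICE_HOURS)
    )
    video_days: int = 3
    video_intensity_scale: float = 1.0
    window_start: time = time(8, 40)
    window_end: time = time(17, 20)
    nonwear_min: int = 20
    valid_day_min: int = 600
    min_valid_days: int = 4
    week_rule: str = "per-week"
    slot_min: int = 15
    record_start: time = time(10, 0)
    record_end: time = time(17, 0)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.accel = dataclasses.replace(self.accel, seed=self.seed)

    @property
    def window(self) -> WorkingWindow:
        return WorkingWindow(self.window_start, self.window_end)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        kwargs: dict = {}
        accel_raw = raw.pop("accel", {})
        for key in ("window_start", "window_end", "record_start", "record_end"):
            if key in raw:
                h, m = map(int, str(raw[key]).split(":"))
                raw[key] = time(h, m)
        if "group_means" in raw:
            raw["group_means"] = {
                g: tuple(v) for g, v in raw["group_means"].items()
            }
        if "office_hours" in raw:
            raw["office_hours"] = {
                (g, ph): float(v)
                for g, d in raw["office_hours"].items()
                for ph, v in d.items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        kwargs.update(raw)
        kwargs["accel"] = AccelSimConfig(seed=raw.get("seed", 0), **accel_raw)
        return cls(**kwargs)

    def accel_config(self, group: str) -> AccelSimConfig:
        sb, lpa, mvpa = self.group_means[group]
        return self.accel.with_means(sb, lpa, mvpa)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"required input {path} is missing; run step {producer!r} first"
        )
    return path


def _step_simulate(cfg: PipelineConfig, out: Path) -> list[Path]:
    written = []
    series = []
    for group in cfg.group_means:
        acfg = cfg.accel_config(group)
        for phase in PHASES:
            series.extend(generate_epoch_series(acfg, group, phase))
    p = out / "epochs.csv"
    oio.write_epoch_csv(series, p)
    written.append(p)
    for phase in PHASES:
        logs = [
            generate_entry_exit_log(
                cfg.accel_config(g), cfg.office_hours[(g, phase)], g, phase
            )
            for g in cfg.group_means
        ]
        p = out / f"entry_exit_{phase}.csv"
        oio.write_entry_exit_csv(pd.concat(logs, ignore_index=True), p)
        written.append(p)
    for phase in PHASES:
        plan = generate_office_plan(phase)
        p = out / f"plan_{phase}.geojson"
        plan.to_geojson(p)
        written.append(p)
        vcfg = VideoSimConfig(
            zone_intensities={
                k: v * cfg.video_intensity_scale
                for k, v in default_zone_intensities(plan).items()
            },
            n_days=cfg.video_days,
            slot_len=cfg.slot_min,
            record_start=cfg.record_start,
            record_end=cfg.record_end,
            seed=cfg.seed + (0 if phase == "pre" else 1),
        )
        det = generate_detection_log(plan, vcfg)
        p = out / f"detections_{phase}.csv"
        oio.write_detection_log(det, p)
        written.append(p)
        log.info("simulate: %s detections (%s)", len(det), phase)
    return written


def _step_accel(cfg: PipelineConfig, out: Path) -> list[Path]:
    series = oio.read_epoch_csv(_require(out / "epochs.csv", "simulate"))
    day_df = summarize_days(
        series,
        window=cfg.window,
        nonwear_min=cfg.nonwear_min,
        valid_day_min=cfg.valid_day_min,
    )
    day_path = out / "day_summaries.csv"
    day_df.to_csv(day_path, index=False)
    phase_frames = []
    for phase in PHASES:
        entry_exit = oio.read_entry_exit_csv(
            _require(out / f"entry_exit_{phase}.csv", "simulate")
        )
        sub = day_df[day_df["phase"] == phase]
        phase_frames.append(
            summarize_phase(
                sub,
                entry_exit,
                window=cfg.window,
                min_valid_days=cfg.min_valid_days,
                rule=cfg.week_rule,
            )
        )
    phase_df = pd.concat(phase_frames, ignore_index=True)
    n_excluded = day_df.groupby(["participant_id", "phase"]).ngroups - len(phase_df)
    log.info("accel: %d participant-phases excluded by validity rules", n_excluded)
    phase_path = out / "phase_summaries.csv"
    phase_df.to_csv(phase_path, index=False)
    return [day_path, phase_path]


def _analysis_space(row_cat: str, label: str) -> str:
    # Table-style analysis spaces: multiple-usage aisles stay distinct zones,
    # other categories pool their zones.
    return label if row_cat == "multiple_usage_aisle" else row_cat


def _step_video(cfg: PipelineConfig, out: Path) -> list[Path]:
    written = []
    for phase in PHASES:
        plan = OfficePlan.from_geojson(
            _require(out / f"plan_{phase}.geojson", "simulate"), name=phase
        )
        det = oio.read_detection_log(
            _require(out / f"detections_{phase}.csv", "simulate")
        )
        counts = aggregate_slot_counts(
            det, plan, start=cfg.record_start, end=cfg.record_end, slot_min=cfg.slot_min
        )
        log.info(
            "video %s: dropped %d out-of-window, %d unassigned detections",
            phase,
            counts.attrs["dropped_out_of_window"],
            counts.attrs["dropped_unassigned"],
        )
        p = out / f"slot_counts_{phase}.csv"
        counts.to_csv(p, index=False)
        written.append(p)
        counts["space"] = [
            _analysis_space(c, l) for c, l in zip(counts["category"], counts["label"])
        ]
        summary = summarize_space(
            counts.assign(label=counts["space"]), level="zone", dispersion="cells"
        )
        p = out / f"space_summary_{phase}.csv"
        summary.to_csv(p, index=False)
        written.append(p)
    return written


def _individual_anova(
    cfg: PipelineConfig, phase_df: pd.DataFrame
) -> dict[str, AnovaResult]:
    results: dict[str, AnovaResult] = {}
    metrics = [m for m in METRIC_LABELS if m in phase_df.columns]
    if "time_in_office_h" in phase_df.columns:
        metrics.append("time_in_office_h")
    for metric in metrics:
        res = mixed_anova(
            phase_df,
            dv=metric,
            subject="participant_id",
            between="group",
            within="phase",
            within_order=["pre", "post"],
        )
        bonferroni_posthoc(
            res,
            phase_df,
            dv=metric,
            subject="participant_id",
            between="group",
            within="phase",
            alpha=cfg.alpha,
            within_order=["pre", "post"],
        )
        results[metric] = res
    return results


def _video_anova(cfg: PipelineConfig, out: Path, phase: str) -> pd.DataFrame:
    counts = pd.read_csv(_require(out / f"slot_counts_{phase}.csv", "video"))
    counts["space"] = [
        _analysis_space(c, l) for c, l in zip(counts["category"], counts["label"])
    ]
    pooled = (
        counts.groupby(["space", "category", "day_index", "slot_index"])["count"]
        .sum()
        .reset_index()
    )
    pooled["subject"] = pooled["space"] + "/day" + pooled["day_index"].astype(str)
    rows = []
    for block, cats in (
        ("aisle", AISLE_CATEGORIES),
        ("workstation", {"dedicated_workstation", "shared_workstation"}),
    ):
        sub = pooled[pooled["category"].isin(cats)].copy()
        entry: dict[str, object] = {"phase": phase, "block": block}
        try:
            if block == "aisle":
                # Aisle areas differ between layouts: pooled zone area per space
                # enters as the covariate, as in the published analysis.
                plan = OfficePlan.from_geojson(out / f"plan_{phase}.geojson", name=phase)
                zone_area = {z.label: z.area_m2 for z in plan.zones}
                zone_space = {
                    z.label: _analysis_space(z.category, z.label) for z in plan.zones
                }
                space_area: dict[str, float] = {}
                for lab, sp in zone_space.items():
                    space_area[sp] = space_area.get(sp, 0.0) + zone_area[lab]
                sub["area_m2"] = sub["space"].map(space_area)
                try:
                    res = mixed_ancova(
                        sub, dv="count", subject="subject", between="space",
                        within="slot_index", covariate="area_m2",
                    )
                    entry["covariate"] = "area_m2"
                except AliasedCovariateError as err:
                    res = mixed_anova(
                        sub, dv="count", subject="subject", between="space",
                        within="slot_index",
                    )
                    entry["covariate"] = f"dropped ({err})"
            else:
                res = mixed_anova(
                    sub, dv="count", subject="subject", between="space",
                    within="slot_index",
                )
            entry["p_space"] = res.p("between")
            entry["p_time"] = res.p("within")
            entry["p_interaction"] = res.p("interaction")
            entry["note"] = res.design_info.get("limitation", "")
            entry["subject_definition"] = "day within space (assumed)"
        except NotApplicableError as err:
            entry["note"] = f"statistical analysis not applicable: {err}"
        rows.append(entry)
    return pd.DataFrame(rows)


def _step_anova(cfg: PipelineConfig, out: Path) -> list[Path]:
    phase_df = pd.read_csv(_require(out / "phase_summaries.csv", "accel"))
    results = _individual_anova(cfg, phase_df)
    table2 = render_table2(phase_df, results)
    p1 = out / "individual_anova.csv"
    table2.to_csv(p1, index=False)
    written = [p1]
    for phase in PHASES:
        vres = _video_anova(cfg, out, phase)
        p = out / f"video_anova_{phase}.csv"
        vres.to_csv(p, index=False)
        written.append(p)
    return written


def _step_report(cfg: PipelineConfig, out: Path) -> list[Path]:
    phase_df = pd.read_csv(_require(out / "phase_summaries.csv", "accel"))
    table1 = render_table1(phase_df[phase_df["phase"] == "pre"])
    p1 = out / "table1_baseline.csv"
    table1.to_csv(p1, index=False)
    counts = pd.read_csv(_require(out / "slot_counts_post.csv", "video"))
    shared = counts[counts["category"] == "shared_workstation"]
    profile = slot_profile(shared)
    p2 = out / "figure3_slot_profiles.png"
    plot_slot_profiles(profile, p2, title="Shared workstations, post-renovation")
    p3 = out / "slot_profiles_post.csv"
    profile.to_csv(p3)
    return [p1, p2, p3]


_STEP_FNS = {
    "simulate": _step_simulate,
    "accel": _step_accel,
    "video": _step_video,
    "anova": _step_anova,
    "report": _step_report,
}


def run_pipeline(
    cfg: PipelineConfig, steps: tuple[str, ...] | list[str] = STEPS
) -> dict[str, str]:
    """Run the requested steps in canonical order and write a manifest.

    Returns the manifest mapping (relative path -> SHA-256). Re-running with
    the same config and seed reproduces identical hashes.
    """
    unknown = set(steps) - set(STEPS)
    if unknown:
        raise ValueError(f"unknown step(s): {sorted(unknown)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for step in STEPS:
        if step not in steps:
            continue
        log.info("running step %s", step)
        written.extend(_STEP_FNS[step](cfg, out))
    manifest = {str(p.relative_to(out)): _sha256(p) for p in written}
    manifest_path = out / "manifest.json"
    existing = {}
    if manifest_path.exists():
        existing = json.loads(manifest_path.read_text())
    existing.update(manifest)
    manifest_path.write_text(json.dumps(existing, indent=1, sort_keys=True))
    return existing
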