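# officeactivity

Analysis pipeline for a workplace natural experiment: how an office
renovation — activity-based working (ABW) with height-adjustable desks —
changes sedentary behaviour (SB), physical activity (PA) and the use of
office space. The package is aimed at researchers in occupational physical
activity and workplace-health epidemiology who work with hip-worn
accelerometer epoch files and camera-based person-detection logs.

It covers three stages, each usable on its own:

1. **Accelerometry** — 60-s MET epoch series → per-day and per-phase
   summaries. Epochs are classified by the standard cut-points
   (SB ≤ 1.5 METs, LPA 1.6–3.0 METs, MVPA ≥ 3.0 METs); non-wear is any run
   of ≥ 20 consecutive minutes below the detectable intensity; a valid day
   has ≥ 10 h wear and a participant-phase is retained with ≥ 4 valid
   weekdays per working week. Prolonged SB is the total time in
   uninterrupted SB bouts of ≥ 30 min. Workday durations are normalised to
   the standard 8:40–17:20 window (520 min = 8.67 h):

   `min/working-hours = observed duration / wearing time × 520`

   so normalised SB + normalised total PA = 520 for every day — an identity
   the pipeline enforces exactly.
2. **Space utilization** — person detections (timestamp + floor coordinate)
   are assigned to labelled office zones (GeoJSON polygons) and aggregated
   into half-open 15-min slots over the 10:00–17:00 recording window
   (28 slots/day); per-space mean ± SE counts per 15 min and per-zone slot
   profiles mirror the usual reporting.
3. **Statistics** — a hand-implemented split-plot (mixed) repeated-measures
   ANOVA: between-subjects factor (group or space) tested against
   subject-within-group error, within factor (phase or slot) and the
   interaction tested against the subject × within residual, with Bonferroni
   pre/post post hoc contrasts, an optional subject-level covariate (zone
   area) in the between stratum, and baseline t / chi-square comparisons.

Because the study's raw data were never deposited, `officeactivity.synthetic`
generates cohorts with the same statistical structure (configurable
group × phase activity composition, bout structure, non-wear gaps, Poisson
detection counts, rectangle floor plans), so the full pipeline runs and is
testable from nothing but a seed.

## Worked example

Simulate a two-arm cohort (29 control / 13 renovation, two phases, 25-min
SB→LPA renovation effect), summarise it and test the group × time
interaction:

```python
import pandas as pd
from officeactivity import (
    AccelSimConfig, generate_epoch_series, summarize_days, summarize_phase,
    mixed_anova, bonferroni_posthoc,
)
from officeactivity.synthetic import GROUP_BASELINE_MEANS

frames = []
for group, n in (("control", 29), ("renovation", 13)):
    sb, lpa, mvpa = GROUP_BASELINE_MEANS[group]
    cfg = AccelSimConfig(seed=1, n_per_group={group: n},
                         working_sb_min=sb, working_lpa_min=lpa,
                         working_mvpa_min=mvpa, effect_sb_change=25.0)
    for phase in ("pre", "post"):
        days = summarize_days(generate_epoch_series(cfg, group, phase))
        frames.append(summarize_phase(days))
summary = pd.concat(frames, ignore_index=True)

print(summary.groupby(["group", "phase"])["sb_min_norm"].agg(["mean", "std"]).round(1))
res = mixed_anova(summary, dv="sb_min_norm", subject="participant_id",
                  between="group", within="phase", within_order=["pre", "post"])
print(res.table.round(4).to_string(index=False))
print(bonferroni_posthoc(res, summary, dv="sb_min_norm",
                         subject="participant_id", between="group",
                         within="phase", within_order=["pre", "post"]).round(4))
```

Output:

```
                   mean   std
group      phase
control    post   374.3  22.1
           pre    373.6  21.4
renovation post   311.5  27.1
           pre    337.5  26.2
                source         SS  df         MS        F   p
               between 43945.6418   1 43945.6418  40.7476 0.0
subjects_within_groups 43139.3306  40  1078.4833      NaN NaN
                within  1194.8933   1  1194.8933 116.6614 0.0
           interaction  3212.6504   1  3212.6504 313.6618 0.0
          within_error   409.6962  40    10.2424      NaN NaN
  between_level    contrast       t  df  p_raw  p_adj  m
0       control pre vs post -0.8007  28 0.4301 0.8601  2
1    renovation pre vs post 28.5626  12 0.0000 0.0000  2
```

Read: the renovation arm's normalised working-hours SB drops from
337.5 to 311.5 min/working-hours (a ~26-min reduction against the
configured 25), the control arm is flat, and the split-plot ANOVA finds a
strong group × time interaction with the post hoc contrast significant only
in the renovation arm.

The same chain is available from the shell:

```bash
officeactivity run-all --seed 1 --outdir results/run
```

which writes the simulated inputs, day/phase summaries, slot-count tables,
ANOVA tables in the study's table layouts, a shared-workstation slot-profile
figure, and a `manifest.json` of SHA-256 hashes (identical on rerun with the
same seed). A YAML config can replace or override any flag; see
`PipelineConfig.from_yaml`.

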