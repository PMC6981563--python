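"""Split-plot (mixed) repeated-measures ANOVA, covariate adjustment,
Bonferroni post hoc contrasts and baseline group comparisons.

The design has one between-subjects factor (intervention group, or office
space) and one within-subjects repeated factor (measurement time, or 15-min
slot). The classical decomposition uses two error strata:

* between-subjects stratum — the between effect tested against
  subject-within-group variation;
* within-subjects stratum — the within effect and the interaction tested
  against the subject x within residual.

With unequal group sizes the weighted (Type II) sums of squares are used.
No sphericity correction is applied; with two within levels sphericity is
moot, and for longer within factors the result carries a limitation flag in
``design_info``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "NotApplicableError",
    "DegenerateDesignError",
    "AliasedCovariateError",
    "split_plot_anova",
    "mixed_anova",
    "mixed_ancova",
    "bonferroni_posthoc",
    "baseline_tests",
]


class NotApplicableError(ValueError):
    """The design cannot support the requested test (e.g. a between level
    with fewer than two subjects)."""


class DegenerateDesignError(ValueError):
    """All responses identical: every SS is zero and F is undefined."""


class AliasedCovariateError(ValueError):
    """The covariate is collinear with the between factor."""


@dataclass
class AnovaResult:
    """ANOVA summary: one row per effect/error stratum plus metadata.

    ``table`` columns: ``source, SS, df, MS, F, p``; error strata carry
    NaN F/p. ``posthoc`` is filled by :func:`bonferroni_posthoc`.
    """

    table: pd.DataFrame
    design_info: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def effect(self, source: str) -> pd.Series:
        return self.table.set_index("source").loc[source]

    def p(self, source: str) -> float:
        return float(self.effect(source)["p"])


def split_plot_anova(y: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Split-plot ANOVA on complete wide-format data.

    Parameters
    ----------
    y : (n_subjects, n_within) array of responses, one row per subject.
    groups : (n_subjects,) array of between-level codes.

    Returns the effect table with sources ``between, subjects_within_groups,
    within, interaction, within_error``. This numpy core is fast enough to be
    called thousands of times in null simulations.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 2:
        raise ValueError("y must be (n_subjects, n_within)")
    n, t = y.shape
    if t < 2:
        raise ValueError("need at least two within levels")
    levels, codes = np.unique(groups, return_inverse=True)
    g = len(levels)
    counts = np.bincount(codes)
    if g < 2:
        raise NotApplicableError("need at least two between levels")
    if np.any(counts < 2):
        bad = [str(levels[i]) for i in np.flatnonzero(counts < 2)]
        raise NotApplicableError(
            f"analysis not applicable: between level(s) {bad} have <2 subjects"
        )
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0.0:
        raise DegenerateDesignError("all responses identical; F undefined")

    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[codes == i].mean() for i in range(g)])
    time_means = y.mean(axis=0)
    cell_means = np.vstack([y[codes == i].mean(axis=0) for i in range(g)])

    ss_between = t * float(np.sum(counts * (group_means - grand) ** 2))
    ss_subj = t * float(np.sum((subj_means - group_means[codes]) ** 2))
    ss_within = n * float(np.sum((time_means - grand) ** 2))
    ss_cells_resid = float(np.sum((y - cell_means[codes]) ** 2))
    ss_inter = ss_total - ss_cells_resid - ss_within - ss_between
    ss_within_total = float(np.sum((y - subj_means[:, None]) ** 2))
    ss_err_w = ss_within_total - ss_within - ss_inter
    # SS obtained by subtraction can round to tiny negatives when a stratum
    # has exactly zero variation; clamp before forming mean squares.
    tiny = 1e-12 * max(ss_total, 1.0)
    ss_inter = 0.0 if abs(ss_inter) < tiny else ss_inter
    ss_err_w = 0.0 if abs(ss_err_w) < tiny else ss_err_w

    df_between, df_subj = g - 1, n - g
    df_within = t - 1
    df_inter = (g - 1) * (t - 1)
    df_err_w = (n - g) * (t - 1)

    ms_subj = ss_subj / df_subj
    ms_err_w = ss_err_w / df_err_w
    if ms_subj == 0 or ms_err_w == 0:
        raise DegenerateDesignError("zero error variance; F undefined")

    def frow(source, ss, df, ms_err, df_err):
        f = (ss / df) / ms_err
        return dict(
            source=source, SS=ss, df=df, MS=ss / df, F=f, p=float(sps.f.sf(f, df, df_err))
        )

    rows = [
        frow("between", ss_between, df_between, ms_subj, df_subj),
        dict(source="subjects_within_groups", SS=ss_subj, df=df_subj,
             MS=ms_subj, F=np.nan, p=np.nan),
        frow("within", ss_within, df_within, ms_err_w, df_err_w),
        frow("interaction", ss_inter, df_inter, ms_err_w, df_err_w),
        dict(source="within_error", SS=ss_err_w, df=df_err_w,
             MS=ms_err_w, F=np.nan, p=np.nan),
    ]
    return pd.DataFrame(rows)


def _pivot_design(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    within_order: list | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.Index, list]:
    """Wide-format pivot with listwise deletion of incomplete subjects."""
    grp_per_subj = data.groupby(subject)[between].nunique()
    if (grp_per_subj > 1).any():
        raise ValueError("each subject must belong to exactly one between level")
    dup = data.groupby([subject, within]).size()
    if (dup > 1).any():
        raise ValueError("at most one observation per subject x within cell")
    piv = data.pivot_table(index=subject, columns=within, values=dv, observed=True)
    if within_order is not None:
        piv = piv[list(within_order)]
    complete = piv.dropna()
    n_dropped = len(piv) - len(complete)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} subject(s) dropped listwise (missing within level)",
            stacklevel=3,
        )
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[complete.index].to_numpy()
    return complete.to_numpy(), groups, complete.index, list(complete.columns)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    within_order: list | None = None,
) -> AnovaResult:
    """Mixed (split-plot) ANOVA from a long-format table.

    Subjects missing any within level are dropped listwise with a warning.
    """
    y, groups, subjects, wlevels = _pivot_design(
        data, dv, subject, between, within, within_order
    )
    table = split_plot_anova(y, groups)
    info = {
        "n_subjects": len(subjects),
        "between_levels": sorted(map(str, np.unique(groups))),
        "within_levels": [str(w) for w in wlevels],
        "sphericity_correction": "none",
    }
    if len(wlevels) > 2:
        info["limitation"] = (
            "no sphericity correction applied with >2 within levels"
        )
    return AnovaResult(table=table, design_info=info)


def mixed_ancova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    covariate: str,
    within_order: list | None = None,
) -> AnovaResult:
    """Split-plot ANOVA with a subject-level covariate in the between stratum.

    The covariate must be constant within subject (e.g. the floor area of a
    space). Its SS is removed from the between-subjects error before testing
    the between effect; the within stratum is unchanged.
    """
    if (data.groupby(subject)[covariate].nunique() > 1).any():
        raise ValueError("covariate must be constant within subject")
    y, groups, subjects, wlevels = _pivot_design(
        data, dv, subject, between, within, within_order
    )
    cov = (
        data.drop_duplicates(subject).set_index(subject)[covariate].loc[subjects]
    ).to_numpy(dtype=float)
    table = split_plot_anova(y, groups)
    n, t = y.shape
    levels, codes = np.unique(groups, return_inverse=True)
    g = len(levels)

    # Subject-level ANCOVA via incremental least squares (scale by t to stay
    # on the observation scale of the split-plot table).
    subj_means = y.mean(axis=1)
    intercept = np.ones(n)
    dummies = np.eye(g)[codes][:, 1:]  # reference coding
    x_full = np.column_stack([intercept, cov, dummies])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise AliasedCovariateError(
            f"covariate {covariate!r} is collinear with between factor; "
            "the group effect cannot be separated from the covariate"
        )

    def sse(x):
        beta, *_ = np.linalg.lstsq(x, subj_means, rcond=None)
        r = subj_means - x @ beta
        return float(r @ r)

    sse_full = sse(x_full)
    sse_no_group = sse(np.column_stack([intercept, cov]))
    sse_no_cov = sse(np.column_stack([intercept, dummies]))
    ss_between_adj = t * (sse_no_group - sse_full)
    ss_cov = t * (sse_no_cov - sse_full)
    ss_err = t * sse_full
    df_err = n - g - 1
    if df_err < 1:
        raise NotApplicableError("too few subjects for covariate adjustment")
    ms_err = ss_err / df_err
    if ms_err == 0:
        raise DegenerateDesignError("zero between-error variance; F undefined")

    def frow(source, ss, df):
        f = (ss / df) / ms_err
        return dict(source=source, SS=ss, df=df, MS=ss / df, F=f,
                    p=float(sps.f.sf(f, df, df_err)))

    between_rows = pd.DataFrame(
        [
            frow("covariate", ss_cov, 1),
            frow("between", ss_between_adj, g - 1),
            dict(source="subjects_within_groups", SS=ss_err, df=df_err,
                 MS=ms_err, F=np.nan, p=np.nan),
        ]
    )
    within_rows = table[table["source"].isin(["within", "interaction", "within_error"])]
    out = pd.concat([between_rows, within_rows], ignore_index=True)
    info = {
        "n_subjects": n,
        "between_levels": sorted(map(str, levels)),
        "within_levels": [str(w) for w in wlevels],
        "covariate": covariate,
        "sphericity_correction": "none",
    }
    if len(wlevels) > 2:
        info["limitation"] = "no sphericity correction applied with >2 within levels"
    return AnovaResult(table=out, design_info=info)


def bonferroni_posthoc(
    result: AnovaResult,
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    alpha: float = 0.05,
    within_order: list | None = None,
) -> pd.DataFrame:
    """Paired pre/post contrasts within each between level, Bonferroni-adjusted.

    Run only when the interaction is significant at ``alpha``; otherwise an
    empty record set (with a note in ``result.design_info``) is returned.
    The family is the set of within-group contrasts, m = number of between
    levels; adjusted p = min(1, raw p * m).
    """
    columns = ["between_level", "contrast", "t", "df", "p_raw", "p_adj", "m"]
    if result.p("interaction") >= alpha:
        result.design_info["posthoc_note"] = (
            f"interaction p >= {alpha}; post hoc tests not run"
        )
        result.posthoc = pd.DataFrame(columns=columns)
        return result.posthoc
    y, groups, subjects, wlevels = _pivot_design(
        data, dv, subject, between, within, within_order
    )
    if len(wlevels) != 2:
        raise ValueError("post hoc pre/post contrasts require two within levels")
    levels = np.unique(groups)
    m = len(levels)
    rows = []
    for lev in levels:
        sub = y[groups == lev]
        t_stat, p_raw = sps.ttest_rel(sub[:, 0], sub[:, 1])
        rows.append(
            dict(
                between_level=str(lev),
                contrast=f"{wlevels[0]} vs {wlevels[1]}",
                t=float(t_stat),
                df=len(sub) - 1,
                p_raw=float(p_raw),
                p_adj=min(1.0, float(p_raw) * m),
                m=m,
            )
        )
    result.posthoc = pd.DataFrame(rows, columns=columns)
    return result.posthoc


def baseline_tests(
    data: pd.DataFrame,
    group: str,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Baseline group comparisons: equal-variance independent t-test for
    continuous variables, Pearson chi-square (no continuity correction) for
    categorical ones. Returns one row per variable with statistic and p."""
    continuous = continuous or []
    categorical = categorical or []
    levels = data[group].unique()
    if len(levels) != 2:
        raise ValueError("baseline tests expect exactly two groups")
    rows = []
    for var in continuous:
        a = data.loc[data[group] == levels[0], var].dropna()
        b = data.loc[data[group] == levels[1], var].dropna()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() != b.mean():
            raise ValueError(f"zero variance in both groups for {var!r}")
        t_stat, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(dict(variable=var, test="t", statistic=float(t_stat), p=float(p)))
    for var in categorical:
        table = pd.crosstab(data[group], data[var])
        if table.size == 0:
            raise ValueError(f"empty contingency table for {var!r}")
        chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        rows.append(
            dict(variable=var, test="chi2", statistic=float(chi2), p=float(p))
        )
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
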