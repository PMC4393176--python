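"""Group-comparison layer for longitudinal per-animal metric tables.

The study design is a two-group (control vs treated), five-timepoint
(baseline, d2, d7, d14, d28) repeated-measures experiment.  Post-occlusion
data (d2–d28) are analysed with a two-way mixed-design repeated-measures
ANOVA — one between-subject factor (group) and one within-subject factor
(time) — with Bonferroni-adjusted per-timepoint group contrasts as post
tests; single-timepoint comparisons use the two-tailed unpaired (pooled
variance) Student's t-test.  Summaries are mean ± SEM.

The mixed ANOVA uses classical sums of squares with subject as the error
stratum for the between factor; no sphericity correction is applied.
Animals missing any included timepoint are dropped complete-case, with a
logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "MixedAnovaResult",
    "summarize",
    "unpaired_t_test",
    "mixed_anova",
    "rm_anova_bonferroni",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("animal", "group", "timepoint", "metric", "value")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table lacks columns {missing}")
    dup = table.duplicated(subset=["animal", "timepoint", "metric"])
    if dup.any():
        raise ValueError(
            "duplicate (animal, timepoint, metric) rows: "
            f"{table.loc[dup, ['animal', 'timepoint', 'metric']].iloc[0].tolist()}"
        )


def summarize(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-(group, timepoint) mean ± SEM of one metric.

    SEM is sd/√n with the sample (ddof=1) standard deviation.
    """
    _check_table(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in the table")
    out = (
        sub.groupby(["group", "timepoint"], sort=True)["value"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    out.insert(0, "metric", metric)
    return out


@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def unpaired_t_test(a, b) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance, not Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(statistic=float(t), df=float(a.size + b.size - 2), pvalue=float(p))


@dataclass
class MixedAnovaResult:
    """ANOVA table plus Bonferroni-adjusted per-timepoint contrasts.

    ``anova`` columns: source (group / time / group:time), ss, df, ms, F, p.
    ``posthoc`` columns: timepoint, t, df, p_raw, p_adj (raw p × number of
    timepoints, capped at 1).
    ``dropped_animals``: animals removed for missing timepoints.
    """

    anova: pd.DataFrame
    posthoc: pd.DataFrame
    dropped_animals: list


def mixed_anova(data: pd.DataFrame) -> pd.DataFrame:
    """Two-way mixed ANOVA on a complete long table.

    ``data`` must have columns animal/group/timepoint/value with every animal
    observed at every timepoint.  Returns the three-effect ANOVA table.
    """
    wide = data.pivot(index="animal", columns="timepoint", values="value")
    if wide.isna().any().any():
        raise ValueError("mixed ANOVA requires complete cases")
    groups = data.drop_duplicates("animal").set_index("animal")["group"]
    y = wide.to_numpy()
    g = groups.loc[wide.index].to_numpy()
    labels = np.unique(g)
    n_subj, n_time = y.shape
    n_groups = labels.size
    if n_groups < 2 or n_time < 2:
        raise ValueError("need >= 2 groups and >= 2 timepoints")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)

    ss_between_subj = n_time * np.sum((subj_mean - grand) ** 2)
    ss_group = 0.0
    ss_int = 0.0
    for lab in labels:
        sel = g == lab
        n_g = sel.sum()
        gmean = y[sel].mean()
        ss_group += n_time * n_g * (gmean - grand) ** 2
        cell = y[sel].mean(axis=0)
        ss_int += n_g * np.sum((cell - gmean - time_mean + grand) ** 2)
    ss_subj_err = ss_between_subj - ss_group

    ss_within_subj = np.sum((y - subj_mean[:, None]) ** 2)
    ss_time = n_subj * np.sum((time_mean - grand) ** 2)
    ss_err = ss_within_subj - ss_time - ss_int

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_time = n_time - 1
    df_int = df_group * df_time
    df_err = df_subj * df_time

    rows = []
    for source, ss, df, err_ss, err_df in (
        ("group", ss_group, df_group, ss_subj_err, df_subj),
        ("time", ss_time, df_time, ss_err, df_err),
        ("group:time", ss_int, df_int, ss_err, df_err),
    ):
        ms = ss / df
        ms_err = err_ss / err_df
        f = ms / ms_err
        p = float(sps.f.sf(f, df, err_df))
        rows.append({"source": source, "ss": ss, "df": df, "ms": ms, "F": f, "p": p})
    return pd.DataFrame(rows)


def rm_anova_bonferroni(
    table: pd.DataFrame,
    metric: str,
    timepoints=("d2", "d7", "d14", "d28"),
    alpha: float = 0.05,
) -> MixedAnovaResult:
    """Repeated-measures group×time analysis of one metric with post tests.

    Restricts the table to ``timepoints``, drops animals not observed at all
    of them (complete-case, logged), runs the mixed ANOVA, and performs an
    unpaired t-test per timepoint with Bonferroni adjustment (× number of
    timepoints, capped at 1).
    """
    _check_table(table)
    timepoints = list(timepoints)
    sub = table[(table["metric"] == metric) & (table["timepoint"].isin(timepoints))]
    if sub.empty:
        raise ValueError(f"metric {metric!r} has no rows at timepoints {timepoints}")
    counts = sub.groupby("animal")["timepoint"].nunique()
    complete = counts[counts == len(timepoints)].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning(
            "mixed ANOVA on %r: dropping %d animal(s) with missing timepoints: %s",
            metric, len(dropped), ", ".join(map(str, dropped)),
        )
    sub = sub[sub["animal"].isin(complete)]
    per_group = sub.drop_duplicates("animal").groupby("group")["animal"].count()
    if (per_group < 2).any() or per_group.size < 2:
        raise ValueError("need >= 2 complete-case animals in each of >= 2 groups")

    anova = mixed_anova(sub)

    labels = sorted(sub["group"].unique())
    if len(labels) != 2:
        raise ValueError("post tests are defined for exactly 2 groups")
    rows = []
    for tp in timepoints:
        at = sub[sub["timepoint"] == tp]
        a = at.loc[at["group"] == labels[0], "value"].to_numpy()
        b = at.loc[at["group"] == labels[1], "value"].to_numpy()
        res = unpaired_t_test(a, b)
        rows.append(
            {
                "timepoint": tp,
                "t": res.statistic,
                "df": res.df,
                "p_raw": res.pvalue,
                "p_adj": min(1.0, res.pvalue * len(timepoints)),
            }
        )
    posthoc = pd.DataFrame(rows)
    posthoc["significant"] = posthoc["p_adj"] < alpha
    return MixedAnovaResult(anova=anova, posthoc=posthoc, dropped_animals=list(dropped))
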