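"""Group-level inference: mixed-design ANOVA and Tukey HSD post hoc.

The mixed design has one between-subject factor (group) and one
within-subject factor (distance, delay or serial order); every retained
subject contributes a measure in every within-factor cell.  Sums of squares
follow the classical partition with a subject-within-group error stratum:

    F_group  = MS_group / MS_subjects(group),   df = (g-1, N-g)
    F_within = MS_within / MS_error,            df = (w-1, (N-g)(w-1))
    F_inter  = MS_interaction / MS_error,       df = ((g-1)(w-1), (N-g)(w-1))

Unequal group sizes are handled through the weighted-means partition (each
subject still has the complete within-factor profile).  No sphericity
correction is applied.  With a single within cell the analysis reduces
exactly to a one-way ANOVA on the between factor.

Post hoc pairwise comparisons use Tukey's HSD with the Tukey-Kramer
adjustment for unequal group sizes and p-values from the studentized-range
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupStatsResult", "mixed_anova", "tukey_posthoc", "one_way_anova"]


@dataclass
class GroupStatsResult:
    """ANOVA factor table plus optional pairwise post hoc table."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"anova": self.anova.to_dict(orient="records")}
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.to_dict(orient="records")
        return out


def _f_row(source, ss, df1, ms_err, df2):
    ms = ss / df1 if df1 > 0 else np.nan
    if ms_err > 0 and df1 > 0:
        f = ms / ms_err
        p = float(sps.f.sf(f, df1, df2))
    elif df1 > 0 and ms == 0.0:
        f, p = 0.0, 1.0
    else:
        f, p = np.nan, np.nan
    return {"source": source, "ss": ss, "df1": df1, "df2": df2, "F": f, "p": p}


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "cell",
    subject: str = "subject_id",
    posthoc: bool = True,
) -> GroupStatsResult:
    """Two-way mixed ANOVA (one between, one within factor).

    Subjects with incomplete within-factor cells are dropped with a warning;
    groups of a single subject are an error.  With one within level this is
    exactly the one-way between-group ANOVA.
    """
    df = table[[subject, between, within, dv]].dropna().copy()
    cells = sorted(df[within].unique())
    w = len(cells)
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == w].index
    if len(complete) < len(counts):
        import warnings

        warnings.warn(
            f"dropping {len(counts) - len(complete)} subject(s) with incomplete cells",
            stacklevel=2,
        )
        df = df[df[subject].isin(complete)]
    # subject x cell matrix and group assignment
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    groups = df.groupby(subject)[between].first().loc[wide.index]
    glabels = sorted(groups.unique())
    g = len(glabels)
    if g < 2:
        raise ValueError("need at least two groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs at least two subjects")
    y = wide.to_numpy(dtype=float)
    n_subj = y.shape[0]
    gm = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[(groups == lab).to_numpy()].mean() for lab in glabels])
    n_per = np.array([int((groups == lab).sum()) for lab in glabels])

    ss_group = w * float(np.sum(n_per * (group_means - gm) ** 2))
    gmean_of = {lab: gmn for lab, gmn in zip(glabels, group_means)}
    subj_group_mean = np.array([gmean_of[lab] for lab in groups])
    ss_subj = w * float(np.sum((subj_means - subj_group_mean) ** 2))

    rows = []
    if w > 1:
        cell_means = y.mean(axis=0)
        gc_means = np.vstack([y[(groups == lab).to_numpy()].mean(axis=0) for lab in glabels])
        ss_within = n_subj * float(np.sum((cell_means - gm) ** 2))
        ss_inter = float(
            np.sum(
                n_per[:, None]
                * (gc_means - group_means[:, None] - cell_means[None, :] + gm) ** 2
            )
        )
        gidx = np.array([glabels.index(lab) for lab in groups])
        resid = y - gc_means[gidx] - subj_means[:, None] + subj_group_mean[:, None]
        ss_err = float(np.sum(resid**2))
        df_err = (n_subj - g) * (w - 1)
        ms_err = ss_err / df_err if df_err > 0 else np.nan
    df_subj = n_subj - g
    ms_subj = ss_subj / df_subj if df_subj > 0 else np.nan
    rows.append(_f_row(between, ss_group, g - 1, ms_subj, df_subj))
    if w > 1:
        rows.append(_f_row(within, ss_within, w - 1, ms_err, df_err))
        rows.append(_f_row(f"{between} * {within}", ss_inter, (g - 1) * (w - 1), ms_err, df_err))
        rows.append(
            {"source": "error (within)", "ss": ss_err, "df1": df_err, "df2": np.nan,
             "F": np.nan, "p": np.nan}
        )
    rows.append(
        {"source": f"subjects({between})", "ss": ss_subj, "df1": df_subj, "df2": np.nan,
         "F": np.nan, "p": np.nan}
    )
    anova = pd.DataFrame(rows)
    ph = None
    if posthoc:
        ph = tukey_posthoc({lab: subj_means[(groups == lab).to_numpy()] for lab in glabels})
    return GroupStatsResult(anova=anova, posthoc=ph)


def one_way_anova(values_by_group: dict) -> GroupStatsResult:
    """One-way between-group ANOVA with Tukey post hoc on subject means."""
    rows = []
    for lab, vals in values_by_group.items():
        for i, v in enumerate(np.asarray(vals, dtype=float)):
            rows.append({"subject_id": f"{lab}_{i}", "group": lab, "cell": 0, "value": v})
    return mixed_anova(pd.DataFrame(rows))


def tukey_posthoc(values_by_group: dict) -> pd.DataFrame:
    """Tukey HSD pairwise table on per-group subject means.

    Uses the pooled within-group variance; unequal n handled by the
    Tukey-Kramer harmonic form; adjusted p from the studentized-range
    distribution with (n_groups, N - n_groups) parameters.  A zero pooled
    variance is flagged (q undefined; p = 1 when the means also tie).
    """
    labels = sorted(values_by_group)
    arrays = {lab: np.asarray(values_by_group[lab], dtype=float) for lab in labels}
    if len(labels) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("Tukey needs >= 2 groups of >= 2 subjects")
    g = len(labels)
    n_total = sum(a.size for a in arrays.values())
    df_err = n_total - g
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    msw = ssw / df_err
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = arrays[labels[i]], arrays[labels[j]]
            diff = float(a.mean() - b.mean())
            if msw == 0.0:
                q = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
                se = 0.0
                degenerate = True
            else:
                se = float(np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size)))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, g, df_err))
                degenerate = False
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": diff,
                    "se": se,
                    "q": q,
                    "p_adj": min(max(p, 0.0), 1.0),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
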