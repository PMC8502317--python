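"""Statistical surface for engagement analyses.

Everything here mirrors the analysis plan of a two-arm school-based
intervention: independent two-group t-tests and Pearson chi-square for
PD vs non-PD comparisons, Pearson correlation of engagement indices with
youth BMI percentile, an additive school/classroom adjustment of BMI
percentile, and a split-plot (mixed) repeated-measures decomposition of
two-timepoint change by group.

No multiple-testing correction is applied anywhere: the reported p-values are
per-comparison, as in the analysis plan this package operationalizes.  Treat
families of comparisons accordingly.

Implementations delegate to scipy.stats, statsmodels and pingouin; the classes
here only standardize the result shape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GroupComparison",
    "RepeatedMeasuresResult",
    "pearson_correlation",
    "two_group_t",
    "chi_square_independence",
    "adjust_bmi_percentile",
    "repeated_measures_by_group",
    "engagement_report",
]


@dataclass
class GroupComparison:
    """Result of a two-or-more-group comparison."""

    test: str  # "t", "welch_t" or "chi2"
    groups: tuple[str, ...]
    n: tuple[int, ...]
    statistic: float
    df: float
    p_value: float
    means: Optional[tuple[float, ...]] = None
    sds: Optional[tuple[float, ...]] = None
    counts: Optional[np.ndarray] = None
    expected: Optional[np.ndarray] = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class RepeatedMeasuresResult:
    """Split-plot decomposition of a group × time repeated-measures design."""

    marginal_means: pd.DataFrame  # index (group, time): mean, se, n
    group: tuple[float, float, float]  # (F, df, p) between-subject effect
    time: tuple[float, float, float]  # within-subject effect
    interaction: tuple[float, float, float]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation is undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def two_group_t(
    x: Sequence[float],
    y: Sequence[float],
    pooled: bool = True,
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Independent two-sample t-test, pooled-variance by default (Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    warns: list[str] = []
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        warns.append("both groups have zero variance; statistic is degenerate")
        if x.mean() == y.mean():
            stat, p = 0.0, 1.0
        else:
            stat = math.inf if x.mean() > y.mean() else -math.inf
            p = 0.0
        df = x.size + y.size - 2 if pooled else float(min(x.size, y.size) - 1)
        return GroupComparison(
            test="t" if pooled else "welch_t",
            groups=labels,
            n=(int(x.size), int(y.size)),
            statistic=stat,
            df=float(df),
            p_value=p,
            means=(float(x.mean()), float(y.mean())),
            sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
            warnings=warns,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=pooled)
    return GroupComparison(
        test="t" if pooled else "welch_t",
        groups=labels,
        n=(int(x.size), int(y.size)),
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        means=(float(x.mean()), float(y.mean())),
        sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
        warnings=warns,
    )


def chi_square_independence(
    table: Sequence[Sequence[float]] | np.ndarray,
    labels: tuple[str, ...] = (),
) -> GroupComparison:
    """Pearson chi-square test of independence on a 2-D contingency table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValidationError("contingency table must be 2-D with at least 2 rows and columns")
    if (obs < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    warns = []
    if (expected < 5).any():
        warns.append(
            f"{int((expected < 5).sum())} cell(s) have expected count < 5; "
            "the chi-square approximation may be poor"
        )
    return GroupComparison(
        test="chi2",
        groups=labels or tuple(f"row{i}" for i in range(obs.shape[0])),
        n=tuple(int(n) for n in obs.sum(axis=1)),
        statistic=float(stat),
        df=float(df),
        p_value=float(p),
        counts=obs,
        expected=expected,
        warnings=warns,
    )


def adjust_bmi_percentile(
    outcomes: pd.DataFrame,
    value_col: str = "bmi_percentile_t0",
    school_col: str = "school",
    classroom_col: str = "classroom",
) -> pd.Series:
    """Remove additive school and classroom effects from a BMI-percentile column.

    Fits an ordinary least-squares model with school and classroom treated as
    unordered factors (classroom labels are taken as globally unique, i.e. not
    nested re-use across schools) and returns residuals plus the grand mean.
    Rows with a missing value are returned as missing.  The adjustment is
    idempotent and preserves the grand mean.
    """
    import statsmodels.formula.api as smf

    df = outcomes[[value_col, school_col, classroom_col]].copy()
    df.columns = ["y", "school", "classroom"]
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    mask = df["y"].notna()
    work = df[mask].astype({"school": str, "classroom": str})
    if work.empty:
        raise ValidationError(f"no non-missing values in {value_col!r}")
    singletons = work.groupby("classroom")["y"].size()
    n_single = int((singletons == 1).sum())
    if n_single:
        warnings.warn(
            f"{n_single} classroom(s) have a single observation and contribute "
            "no within-group information to the adjustment",
            stacklevel=2,
        )
    if work["school"].nunique() == 1 and work["classroom"].nunique() == 1:
        adjusted_values = work["y"]  # centering no-op
    else:
        fit = smf.ols("y ~ C(school) + C(classroom)", data=work).fit()
        adjusted_values = fit.resid + work["y"].mean()
    adjusted = pd.Series(np.nan, index=outcomes.index, name=f"adjusted_{value_col}")
    adjusted[mask] = adjusted_values
    return adjusted


def repeated_measures_by_group(
    data: pd.DataFrame,
    subject_col: str = "parent_id",
    group_col: str = "pd",
    value_cols: tuple[str, str] = ("bmi_percentile_t0", "bmi_percentile_t2"),
) -> RepeatedMeasuresResult:
    """Two-timepoint split-plot ANOVA: group, time, and group × time effects.

    Requires complete pairs; subjects missing either timepoint are dropped.
    The between-subject factor must have exactly two levels with at least two
    complete subjects each.  Marginal means and standard errors per
    group × time are reported alongside the three F-tests.
    """
    import pingouin as pg

    t0_col, t1_col = value_cols
    work = data[[subject_col, group_col, t0_col, t1_col]].dropna()
    groups = sorted(work[group_col].unique(), key=str)
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups}")
    sizes = work.groupby(group_col).size()
    if (sizes < 2).any():
        raise ValidationError("each group needs at least 2 subjects with complete pairs")

    long = work.melt(
        id_vars=[subject_col, group_col],
        value_vars=[t0_col, t1_col],
        var_name="time",
        value_name="y",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=long, dv="y", within="time", between=group_col, subject=subject_col
        ).set_index("Source")

    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"

    def _fx(source: str) -> tuple[float, float, float]:
        row = aov.loc[source]
        return float(row["F"]), float(row["DF1"]), float(row[p_col])

    mm = (
        long.groupby([group_col, "time"])["y"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .assign(se=lambda d: d["sd"] / np.sqrt(d["n"]))
        [["mean", "se", "n"]]
    )
    return RepeatedMeasuresResult(
        marginal_means=mm,
        group=_fx(group_col),
        time=_fx("time"),
        interaction=_fx("Interaction"),
    )


def engagement_report(scores: pd.DataFrame, pooled_t: bool = True) -> dict:
    """PD vs non-PD comparison blocks plus engagement–BMI correlations.

    Expects the per-parent table produced by
    :func:`engage.scoring.score_cohort`.  Produces, when the data allow:

    * mean ± SD of standardized PPP/PEI for PD and non-PD parents with the
      independent t-test;
    * per-activity participation (any vs none) cross-tabulated against PD
      status with the chi-square test, among parents offered that activity;
    * Pearson correlations of standardized PPP and PEI with baseline youth
      BMI percentile among engaged parents.
    """
    report: dict = {"n_parents": int(len(scores))}
    pd_mask = scores["pd"].astype(bool)
    report["n_pd"] = int(pd_mask.sum())

    def _cmp_block(col: str) -> Optional[dict]:
        a = scores.loc[pd_mask, col].dropna()
        b = scores.loc[~pd_mask, col].dropna()
        if len(a) < 2 or len(b) < 2:
            return None
        res = two_group_t(a, b, pooled=pooled_t, labels=("pd", "non_pd"))
        return {
            "pd_mean": res.means[0], "pd_sd": res.sds[0], "pd_n": res.n[0],
            "non_pd_mean": res.means[1], "non_pd_sd": res.sds[1], "non_pd_n": res.n[1],
            "t": res.statistic, "df": res.df, "p": res.p_value,
        }

    report["index_comparisons"] = {
        col: block
        for col in ("std_ppp", "std_pei", "pei", "ppp")
        if (block := _cmp_block(col)) is not None
    }

    activity_blocks = {}
    for col in scores.columns:
        if not col.startswith("pts_"):
            continue
        offered = scores[col].notna()
        if offered.sum() == 0:
            continue
        did = scores.loc[offered, col] > 0
        tab = pd.crosstab(pd_mask[offered], did)
        block = {"n_offered": int(offered.sum()), "n_participated": int(did.sum())}
        if tab.shape == (2, 2) and (tab.to_numpy().sum(axis=0) > 0).all():
            res = chi_square_independence(tab.to_numpy(), labels=("non_pd", "pd"))
            block.update({"chi2": res.statistic, "df": res.df, "p": res.p_value})
        activity_blocks[col.removeprefix("pts_")] = block
    report["activity_by_pd"] = activity_blocks

    if "bmi_percentile_t0" in scores.columns:
        engaged = scores[(scores["ppp"] > 0) & scores["bmi_percentile_t0"].notna()]
        corr = {}
        for col in ("std_ppp", "std_pei"):
            vals = engaged[[col, "bmi_percentile_t0"]].dropna()
            if len(vals) >= 3 and vals[col].nunique() > 1 and vals["bmi_percentile_t0"].nunique() > 1:
                r, p = pearson_correlation(vals[col], vals["bmi_percentile_t0"])
                corr[col] = {"r": r, "p": p, "n": int(len(vals))}
        report["bmi_correlations"] = corr
    return report
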