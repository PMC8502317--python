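"""Frozen reference values and independent textbook-formula oracles.

The oracles here deliberately avoid the library paths they check: brute-force
enumeration for engagement intensity, direct sum formulas for the statistics,
and the classical sums-of-squares decomposition for the split-plot design.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Published per-arm standardization maxima:
# (max_ppp, max_pei, program_ppp, program_pei, evaluation_ppp, evaluation_pei)
# for each of the 31 cohort x school arms of the canonical catalog.
# ---------------------------------------------------------------------------
ARM_MAXIMA = {
    ("1", "1"): (2, 12, 0, 0, 2, 12), ("1", "2"): (1, 6, 0, 0, 1, 6),
    ("1", "3"): (2, 12, 0, 0, 2, 12), ("1", "4"): (2, 12, 1, 6, 1, 6),
    ("1", "5"): (2, 12, 1, 6, 1, 6), ("1", "6"): (2, 12, 1, 6, 1, 6),
    ("1", "7"): (1, 6, 0, 0, 1, 6), ("1", "8"): (3, 18, 1, 6, 2, 12),
    ("2", "1"): (5, 30, 1, 6, 4, 24), ("2", "2"): (6, 36, 3, 18, 3, 18),
    ("2", "3"): (5, 30, 1, 6, 4, 24), ("2", "4"): (7, 42, 4, 24, 3, 18),
    ("2", "5"): (5, 30, 2, 12, 3, 18), ("2", "6"): (5, 30, 2, 12, 3, 18),
    ("2", "7"): (6, 36, 3, 18, 3, 18), ("2", "8"): (8, 48, 4, 24, 4, 24),
    ("3", "1"): (5, 30, 1, 6, 4, 24), ("3", "2"): (6, 36, 3, 18, 3, 18),
    ("3", "3"): (5, 30, 1, 6, 4, 24), ("3", "4"): (3, 18, 0, 0, 3, 18),
    ("3", "5"): (5, 30, 2, 12, 3, 18), ("3", "6"): (5, 30, 2, 12, 3, 18),
    ("3", "7"): (6, 36, 3, 18, 3, 18), ("3", "8"): (8, 48, 4, 24, 4, 24),
    ("4", "1"): (4, 24, 0, 0, 4, 24), ("4", "2"): (3, 18, 0, 0, 3, 18),
    ("4", "3"): (4, 24, 0, 0, 4, 24), ("4", "4"): (3, 18, 0, 0, 3, 18),
    ("4", "6"): (4, 24, 1, 6, 3, 18), ("4", "7"): (3, 18, 0, 0, 3, 18),
    ("4", "8"): (5, 30, 1, 6, 4, 24),
}

#: Published intensity factors of the eight canonical activities.
INTENSITY_FACTORS = {
    "family_fun_nights": 3,
    "action_packs": 2,
    "recipes": 2,
    "about_eating": 1,
    "surveys": 2,
    "parent_diet": 1,
    "youth_diet": 1,
    "accelerometry": 2,
}


def brute_force_pei(record, catalogs) -> int:
    """Engagement intensity by explicit enumeration, no scoring-module calls
    except the frequency rule itself (re-evaluated bin by bin here)."""
    total = 0
    arm = catalogs.arm(record.cohort_id, record.school_id)
    for name in arm.offered:
        act = catalogs.activity(name)
        count = record.counts.get(name, 0)
        rule = act.frequency_rule
        if rule.kind == "per_occasion":
            pts = count if isinstance(count, int) else sum(count)
        else:
            counts = [count] if isinstance(count, int) else list(count)
            if rule.kind == "binned":
                counts = [sum(counts)]
            pts = 0
            for c in counts:
                for lo, hi, p in rule.bins:
                    if lo <= c <= hi:
                        pts += p
                        break
        total += pts * INTENSITY_FACTORS.get(name, act.intensity_factor)
    return total


def pearson_oracle(x, y) -> tuple[float, float]:
    """Textbook product-moment sum formula plus the t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = math.sqrt(n * (x * x).sum() - sx**2) * math.sqrt(n * (y * y).sum() - sy**2)
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as tdist

    return r, 2 * tdist.sf(abs(t), n - 2)


def pooled_t_oracle(x, y) -> tuple[float, float, float]:
    """Hand-computed pooled-variance two-sample t: (t, df, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    s1 = ((x - x.mean()) ** 2).sum() / (n1 - 1)
    s2 = ((y - y.mean()) ** 2).sum() / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    from scipy.stats import t as tdist

    return t, df, 2 * tdist.sf(abs(t), df)


def chi2_oracle(table) -> tuple[float, float, float]:
    """Direct sum of (O-E)^2/E over all cells: (chi2, df, p)."""
    obs = np.asarray(table, float)
    total = obs.sum()
    chi2 = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            chi2 += (obs[i, j] - e) ** 2 / e
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    from scipy.stats import chi2 as chi2dist

    return chi2, df, chi2dist.sf(chi2, df)


def split_plot_oracle(y: np.ndarray, n_per_group: int):
    """Classical sums-of-squares split-plot decomposition (balanced case).

    ``y`` has shape (g * n, t): subjects stacked by group, columns are
    timepoints.  Returns ((F, df1, p) for group, time, interaction).
    """
    from scipy.stats import f as fdist

    t = y.shape[1]
    g = y.shape[0] // n_per_group
    n = n_per_group
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_of = np.repeat(np.arange(g), n)
    group_means = np.array([subj_means[group_of == k].mean() for k in range(g)])
    time_means = y.mean(axis=0)
    cell_means = np.array([y[group_of == k].mean(axis=0) for k in range(g)])

    ss_between = t * ((subj_means - grand) ** 2).sum()
    ss_group = t * n * ((group_means - grand) ** 2).sum()
    ss_subj = ss_between - ss_group
    ss_time = g * n * ((time_means - grand) ** 2).sum()
    ss_int = n * (
        (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
    ).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_between - ss_time - ss_int

    df_group, df_subj = g - 1, g * n - g
    df_time = t - 1
    df_int = (g - 1) * (t - 1)
    df_err = (g * n - g) * (t - 1)

    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    f_time = (ss_time / df_time) / (ss_err / df_err)
    f_int = (ss_int / df_int) / (ss_err / df_err)
    return (
        (f_group, df_group, fdist.sf(f_group, df_group, df_subj)),
        (f_time, df_time, fdist.sf(f_time, df_time, df_err)),
        (f_int, df_int, fdist.sf(f_int, df_int, df_err)),
    )
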