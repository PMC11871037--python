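"""Cohort statistics with the dam (litter) as experimental unit.

Littermates share a developmental environment and are not independent, so
all group comparisons first average same-sex siblings within each dam and
then treat dams as the observations. Endpoints are compared by one-way
ANOVA across diet/exposure groups with Tukey's HSD for pairwise contrasts,
and by two-way ANOVA (sex x group, type-II sums of squares to tolerate
unbalanced litters) for sex effects. Time courses are summarised by
partial trapezoidal AUCs before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from tracegtt.errors import DomainError, InsufficientDataError

ALPHA = 0.05


def auc_partial(
    times: np.ndarray,
    values: np.ndarray,
    t_start: float,
    t_end: float,
) -> float:
    """Trapezoidal AUC of raw measured points restricted to [t_start, t_end].

    Values at the window edges are obtained by linear interpolation when
    the edges fall between samples.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if t_end <= t_start:
        raise DomainError("empty or inverted AUC window")
    if t_start < times.min() or t_end > times.max():
        raise DomainError("AUC window extends beyond the sampled range")
    inside = (times > t_start) & (times < t_end)
    t = np.concatenate([[t_start], times[inside], [t_end]])
    v = np.interp(t, times, values)
    return float(np.trapezoid(v, t))


def dam_average(
    df: pd.DataFrame,
    value: str,
    by: tuple[str, ...] = ("group", "sex", "dam_id"),
) -> pd.DataFrame:
    """Average same-sex siblings within each dam (litter) for one endpoint."""
    missing = set(by) | {value}
    missing -= set(df.columns)
    if missing:
        raise DomainError(f"missing columns {sorted(missing)}")
    return df.groupby(list(by), as_index=False, observed=True)[value].mean()


def one_way_anova_tukey(
    values_by_group: dict[str, np.ndarray],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """One-way ANOVA F-test plus Tukey HSD pairwise contrasts.

    Input arrays should already be dam-averaged. Returns a tidy table with
    one ``anova`` row (F, p) and one row per pairwise contrast (mean
    difference, adjusted p, significance flag at two-sided alpha).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if a.size < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 dams")

    f_stat, p = sps.f_oneway(*arrays)
    rows = [{"contrast": "anova", "statistic": float(f_stat), "p": float(p),
             "p_adjusted": float(p), "significant": bool(p < alpha)}]

    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(groups, arrays)])
    tuk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    summ = tuk.summary().data[1:]
    for row in summ:
        g1, g2, meandiff, p_adj, lower, upper, reject = row
        rows.append({
            "contrast": f"{g2} - {g1}",
            "statistic": float(meandiff),
            "p": float(p_adj),
            "p_adjusted": float(p_adj),
            "significant": bool(reject),
        })
    return pd.DataFrame(rows)


def two_way_anova(
    df: pd.DataFrame,
    value: str,
    sex_col: str = "sex",
    group_col: str = "group",
) -> pd.DataFrame:
    """Two-way ANOVA (sex, group, sex x group) on dam-averaged values.

    Uses type-II sums of squares, which are invariant to cell imbalance
    from litter attrition and coincide with type-I in balanced designs.
    """
    counts = df.groupby([sex_col, group_col], observed=True)[value].count()
    if (counts < 2).any() or counts.size < 4:
        raise InsufficientDataError(
            "two-way ANOVA needs >= 2 dams in every sex x group cell"
        )
    data = df.rename(columns={value: "_y", sex_col: "_sex", group_col: "_grp"})
    model = smf.ols("_y ~ C(_sex) * C(_grp)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    names = {"C(_sex)": "sex", "C(_grp)": "group", "C(_sex):C(_grp)": "sex x group"}
    for key, label in names.items():
        out.append({
            "effect": label,
            "F": float(table.loc[key, "F"]),
            "p": float(table.loc[key, "PR(>F)"]),
            "significant": bool(table.loc[key, "PR(>F)"] < ALPHA),
        })
    return pd.DataFrame(out)
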