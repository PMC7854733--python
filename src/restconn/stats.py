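"""Group-level statistics for connectivity studies.

Two-sample Student t (pooled variance, from raw samples or printed
summary statistics), Cohen's d, one-way ANOVA, balanced mixed-design
(split-plot) ANOVA with a between-subject group factor and a
within-subject factor such as network cost, partial eta squared
(SS_effect / (SS_effect + SS_error)), Pearson brain-behavior
correlation, and a priori per-group sample size for a two-sample t.

All p-values are two-sided and uncorrected; Bonferroni/FDR adjustment
across a family of tests is available as an explicit helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "StatResult",
    "summarize",
    "t_from_summary",
    "t_from_samples",
    "one_way_anova",
    "partial_eta_from_F",
    "mixed_anova",
    "pearson_r",
    "n_per_group",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n, mean, and standard deviation (ddof=1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class StatResult:
    """A t or F statistic with df, two-sided p and an effect size."""

    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    effect_size_kind: str  # "cohen_d" or "partial_eta_sq"
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.effect_size_kind == "partial_eta_sq" and not (
            0 <= self.effect_size <= 1
        ):
            raise ValueError("partial eta squared must lie in [0, 1]")


def summarize(x) -> GroupSummary:
    x = np.asarray(x, dtype=float)
    return GroupSummary(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


def t_from_summary(a: GroupSummary, b: GroupSummary, name: str = "") -> StatResult:
    """Student pooled-variance two-sample t from summary statistics.

    t = (m_a - m_b) / (s_p sqrt(1/n_a + 1/n_b)), df = n_a + n_b - 2;
    Cohen's d = (m_a - m_b) / s_p.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    if se == 0:
        raise ValueError("zero pooled variance: t undefined")
    t = (a.mean - b.mean) / se
    d = (a.mean - b.mean) / math.sqrt(sp2)
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(
        statistic=t, df=(df,), p=float(p), effect_size=d,
        effect_size_kind="cohen_d", name=name,
    )


def t_from_samples(x, y, name: str = "") -> StatResult:
    """Pooled two-sample t from raw samples (via their summaries)."""
    return t_from_summary(summarize(x), summarize(y), name=name)


def one_way_anova(groups: list, name: str = "") -> StatResult:
    """One-way between-subjects ANOVA with partial eta squared."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1 = len(arrs) - 1
    df2 = allv.size - len(arrs)
    if ss_within == 0 and ss_between == 0:
        f = 0.0
    else:
        ms_within = ss_within / df2
        if ms_within == 0:
            raise ValueError("zero within-group variance: F undefined")
        f = (ss_between / df1) / ms_within
    p = float(sps.f.sf(f, df1, df2))
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) else 0.0
    return StatResult(
        statistic=float(f), df=(df1, df2), p=p, effect_size=float(eta),
        effect_size_kind="partial_eta_sq", name=name,
    )


def partial_eta_from_F(F: float, df1: float, df2: float) -> float:
    """Partial eta squared recovered from an F statistic:
    eta_p^2 = F df1 / (F df1 + df2)."""
    if F < 0 or df1 < 1 or df2 < 1:
        raise ValueError("require F >= 0 and dfs >= 1")
    return F * df1 / (F * df1 + df2)


def _check_balanced(table: pd.DataFrame) -> tuple[list, list, np.ndarray]:
    """Validate a balanced complete split-plot table; return group
    labels, within levels, and values as (groups, subjects, levels)."""
    required = {"subject", "group", "level", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    groups_per_subject = table.groupby("subject")["group"].nunique()
    if (groups_per_subject != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    levels = sorted(table["level"].unique())
    counts = table.groupby(["subject", "level"]).size()
    if (counts != 1).any() or set(
        table.groupby("subject")["level"].nunique()
    ) != {len(levels)}:
        raise ValueError("each subject needs every within-factor level exactly once")
    groups = sorted(table["group"].unique())
    sizes = table.drop_duplicates("subject").groupby("group").size()
    if sizes.nunique() != 1:
        raise ValueError("groups must be of equal size (balanced design)")
    n = int(sizes.iloc[0])
    cube = np.empty((len(groups), n, len(levels)))
    for gi, g in enumerate(groups):
        sub = table[table["group"] == g]
        subjects = sorted(sub["subject"].unique())
        piv = sub.pivot(index="subject", columns="level", values="value")
        cube[gi] = piv.loc[subjects, levels].to_numpy(dtype=float)
    return groups, levels, cube


def mixed_anova(table: pd.DataFrame) -> dict[str, StatResult]:
    """Balanced mixed-design (split-plot) ANOVA.

    Long table with columns subject, group, level, value.  Returns
    StatResults for the between-subject "group" effect (error term:
    subjects within groups), the within-subject "within" effect and the
    "interaction" (error term: within x subjects).  Partial eta squared
    uses each effect's own error term.  No sphericity correction is
    applied.
    """
    groups, levels, y = _check_balanced(table)
    G, n, J = y.shape
    grand = y.mean()
    subj_means = y.mean(axis=2)          # (G, n)
    group_means = y.mean(axis=(1, 2))    # (G,)
    level_means = y.mean(axis=(0, 1))    # (J,)
    cell_means = y.mean(axis=1)          # (G, J)

    ss_group = n * J * ((group_means - grand) ** 2).sum()
    ss_subj = J * ((subj_means - group_means[:, None]) ** 2).sum()
    ss_within = G * n * ((level_means - grand) ** 2).sum()
    ss_inter = n * (
        (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
    ).sum()
    resid = (
        y
        - subj_means[:, :, None]
        - cell_means[:, None, :]
        + group_means[:, None, None]
    )
    ss_err_within = (resid**2).sum()

    df_group, df_subj = G - 1, G * (n - 1)
    df_level, df_inter = J - 1, (G - 1) * (J - 1)
    df_err_within = G * (n - 1) * (J - 1)

    def result(ss_eff, df_eff, ss_err, df_err, name):
        ms_err = ss_err / df_err
        if ms_err == 0:
            raise ValueError(f"zero error variance for {name}: F undefined")
        f = (ss_eff / df_eff) / ms_err
        return StatResult(
            statistic=float(f),
            df=(df_eff, df_err),
            p=float(sps.f.sf(f, df_eff, df_err)),
            effect_size=float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err else 0.0,
            effect_size_kind="partial_eta_sq",
            name=name,
        )

    return {
        "group": result(ss_group, df_group, ss_subj, df_subj, "group"),
        "within": result(ss_within, df_level, ss_err_within, df_err_within, "within"),
        "interaction": result(
            ss_inter, df_inter, ss_err_within, df_err_within, "interaction"
        ),
    }


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def n_per_group(
    d: float, alpha: float = 0.05, power: float = 0.90, method: str = "normal"
) -> int:
    """Per-group sample size for a two-sided two-sample t at effect d.

    Default: normal approximation n = ceil(2 ((z_{1-a/2} + z_pow)/d)^2).
    ``method='exact'`` iterates the noncentral-t power function instead
    (can differ by about one subject).
    """
    if not d > 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if method == "normal":
        z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
        return math.ceil(2 * (z / d) ** 2)
    if method == "exact":
        for n in range(2, 100000):
            df = 2 * n - 2
            nc = d * math.sqrt(n / 2)
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            pw = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
            if pw >= power:
                return n
        raise RuntimeError("sample size search did not converge")
    raise ValueError("method must be 'normal' or 'exact'")


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Opt-in multiple-comparison adjustment (bonferroni or fdr_bh)."""
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests(np.asarray(pvalues, dtype=float), method=method)
    return adj
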