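"""The study's statistical battery on outcome trajectories.

Normality screening (one-sample Kolmogorov-Smirnov against a normal with
moments estimated from the sample), one- and two-way ANOVA, one- and
two-way ANCOVA with the day-2 outcome as covariate, Bonferroni post hoc
adjustment, and effect sizes.

The effect size reported alongside every F test is partial eta-squared,
SS_effect / (SS_effect + SS_error) — the conventional companion of
ANOVA/ANCOVA tables.  ANCOVA is fitted as a general linear model with a
single pooled covariate slope (no slope-by-group interaction).  Factorial
models use type-III sums of squares with sum-to-zero contrasts so that
unbalanced designs (attrition) are handled sensibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class TestResult:
    """One hypothesis-test result row."""

    effect: str
    statistic: float
    df: tuple
    pvalue: float
    effect_size: float | None = None  # partial eta-squared
    contrasts: pd.DataFrame | None = None

    def __repr__(self) -> str:  # compact table-style line
        es = f", pes={self.effect_size:.3f}" if self.effect_size is not None else ""
        return (f"TestResult({self.effect}: F/D={self.statistic:.4g}, "
                f"df={self.df}, p={self.pvalue:.4g}{es})")


def ks_normality(sample, alpha: float = 0.05) -> TestResult:
    """One-sample KS test of normality with estimated mean and SD."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError(f"need at least 5 observations, got {x.size}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("sample is constant; normality test undefined")
    stat, p = sstats.kstest(x, "norm", args=(np.mean(x), sd))
    return TestResult(effect="normality", statistic=float(stat),
                      df=(x.size,), pvalue=float(p))


def _as_groups(data, value: str = "value", group: str = "group") -> dict:
    if isinstance(data, dict):
        return {k: np.asarray(v, dtype=float) for k, v in data.items()}
    df = pd.DataFrame(data)
    return {k: g[value].to_numpy(dtype=float) for k, g in df.groupby(group,
                                                                     observed=True)}


def one_way_anova(data, value: str = "value", group: str = "group",
                  posthoc: bool = False) -> TestResult:
    """One-way fixed-effects ANOVA with partial eta-squared.

    ``data`` is either a mapping of group label to sample or a tidy frame
    with ``value`` and ``group`` columns.  ``posthoc=True`` attaches
    Bonferroni-adjusted pairwise t contrasts using the pooled within-group
    error term.
    """
    groups = _as_groups(data, value, group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    samples = list(groups.values())
    stat, p = sstats.f_oneway(*samples)
    allv = np.concatenate(samples)
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in samples)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples)
    k, n = len(samples), allv.size
    pes = ss_between / (ss_between + ss_within) if ss_between + ss_within > 0 else 0.0
    contrasts = _pairwise_bonferroni(groups, ss_within, n - k) if posthoc else None
    return TestResult(effect=group, statistic=float(stat), df=(k - 1, n - k),
                      pvalue=float(p), effect_size=float(pes),
                      contrasts=contrasts)


def _pairwise_bonferroni(groups: dict, ss_within: float, df_err: int) -> pd.DataFrame:
    """Pairwise t contrasts on the pooled error term, Bonferroni-adjusted."""
    mse = ss_within / df_err
    rows = []
    pairs = list(combinations(sorted(groups), 2))
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        se = np.sqrt(mse * (1 / va.size + 1 / vb.size))
        t = (va.mean() - vb.mean()) / se
        p = 2 * sstats.t.sf(abs(t), df_err)
        rows.append({"a": a, "b": b, "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out["p_raw"].tolist(), m=len(pairs))
    return out


def _typ3_table(model_fit) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return anova_lm(model_fit, typ=3)


def _results_from_table(table: pd.DataFrame, label_map: dict) -> list[TestResult]:
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = int(table.loc["Residual", "df"])
    out = []
    for row_name, effect in label_map.items():
        if row_name not in table.index:
            continue
        ss = float(table.loc[row_name, "sum_sq"])
        df = int(table.loc[row_name, "df"])
        out.append(TestResult(
            effect=effect,
            statistic=float(table.loc[row_name, "F"]),
            df=(df, df_err),
            pvalue=float(table.loc[row_name, "PR(>F)"]),
            effect_size=ss / (ss + ss_err) if ss + ss_err > 0 else 0.0,
        ))
    return out


def two_way_anova(data: pd.DataFrame, value: str = "value",
                  factor_a: str = "day", factor_b: str = "group") -> list[TestResult]:
    """Two-way fixed-effects ANOVA (type-III, sum coding) with interaction."""
    df = pd.DataFrame(data).dropna(subset=[value])
    fa = f"C(Q('{factor_a}'), Sum)"
    fb = f"C(Q('{factor_b}'), Sum)"
    fit = smf.ols(f"Q('{value}') ~ {fa} * {fb}", data=df).fit()
    table = _typ3_table(fit)
    return _results_from_table(table, {
        fa: factor_a,
        fb: factor_b,
        f"{fa}:{fb}": f"{factor_a}:{factor_b}",
    })


def ancova(data: pd.DataFrame, value: str = "value", group: str = "group",
           covariate: str = "covariate",
           timepoint: str | None = None) -> list[TestResult]:
    """One- or two-way ANCOVA with a pooled covariate slope.

    Adjusts the group (and, if given, timepoint) effect for a baseline
    covariate — in the study design, the day-2 value of the same outcome.
    If the covariate is constant the model degenerates to an ANOVA and a
    warning is emitted.
    """
    df = pd.DataFrame(data).dropna(subset=[value])
    if df[covariate].nunique() <= 1:
        warnings.warn(
            "covariate is constant; ANCOVA degenerates to ANOVA",
            stacklevel=2,
        )
        if timepoint is None:
            return [one_way_anova(df, value=value, group=group)]
        return two_way_anova(df, value=value, factor_a=timepoint, factor_b=group)
    terms = [f"Q('{covariate}')", f"C(Q('{group}'), Sum)"]
    labels = {f"Q('{covariate}')": covariate, f"C(Q('{group}'), Sum)": group}
    if timepoint is not None:
        terms.append(f"C(Q('{timepoint}'), Sum)")
        labels[f"C(Q('{timepoint}'), Sum)"] = timepoint
    fit = smf.ols(f"Q('{value}') ~ " + " + ".join(terms), data=df).fit()
    return _results_from_table(_typ3_table(fit), labels)


def bonferroni(pvalues, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, p * m)``, order-preserving."""
    p = list(pvalues)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"m={m} is smaller than the number of comparisons {len(p)}")
    return [min(1.0, float(pi) * m) for pi in p]
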