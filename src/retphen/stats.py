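"""Group-comparison reporting over phenotype feature tables.

Thin glue around standard tests: one-way ANOVA, two-way ANOVA (via
statsmodels OLS), and Kruskal–Wallis, each followed by Bonferroni-
corrected pairwise post-hoc comparisons (Welch t for the ANOVA designs,
Mann–Whitney U for the nonparametric one).  Significance stars follow
the conventional thresholds *: p ≤ 0.05, **: p ≤ 0.01, ***: p ≤ 0.001,
****: p ≤ 0.0001.  An ANOVA on log-transformed values is available as
a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "bonferroni", "stars"]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    """Significance stars for an (adjusted) p-value; 'ns' otherwise."""
    if not np.isfinite(p):
        return "ns"
    for thr, s in _STAR_THRESHOLDS:
        if p <= thr:
            return s
    return "ns"


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m·p)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p_raw)


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    groups: tuple[str, ...]
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if np.isfinite(self.p_raw) and self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p-value cannot be below the raw one")

    @property
    def stars(self) -> str:
        return stars(self.p_adjusted)


def _group_arrays(table: pd.DataFrame, value: str, group: str):
    out = {}
    for name, sub in table.groupby(group, dropna=False):
        arr = sub[value].dropna().to_numpy(dtype=float)
        out[str(name)] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for name, arr in out.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    return out


def compare_groups(table: pd.DataFrame,
                   value: str,
                   group: str,
                   design: str = "oneway",
                   second_factor: str | None = None,
                   log_transform: bool = False) -> list[ComparisonResult]:
    """Omnibus test plus Bonferroni-adjusted pairwise post-hocs.

    ``design`` is 'oneway', 'twoway' (requires ``second_factor``) or
    'nonparametric' (Kruskal–Wallis).  The first result row is the
    omnibus test (its p is reported unadjusted); subsequent rows are
    the pairwise comparisons, adjusted for their own count.
    """
    table = table.copy()
    if log_transform:
        if (table[value] <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        table[value] = np.log(table[value])
    groups = _group_arrays(table, value, group)
    names = sorted(groups)
    results: list[ComparisonResult] = []

    if design == "oneway":
        stat, p = sps.f_oneway(*(groups[n] for n in names))
        omnibus = ("one-way ANOVA", stat, p)
        pair_test = _welch
    elif design == "twoway":
        if second_factor is None:
            raise ValueError("twoway design needs second_factor")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = table.rename(columns={value: "y", group: "g1", second_factor: "g2"})
        model = smf.ols("y ~ C(g1) * C(g2)", data=d).fit()
        an = sm.stats.anova_lm(model, typ=2)
        stat = float(an.loc["C(g1)", "F"])
        p = float(an.loc["C(g1)", "PR(>F)"])
        omnibus = ("two-way ANOVA (main effect)", stat, p)
        pair_test = _welch
    elif design == "nonparametric":
        stat, p = sps.kruskal(*(groups[n] for n in names))
        omnibus = ("Kruskal-Wallis", stat, p)
        pair_test = _mannwhitney
    else:
        raise ValueError(f"unknown design {design!r}")

    results.append(ComparisonResult(parameter=value, groups=tuple(names),
                                    test=omnibus[0], statistic=float(omnibus[1]),
                                    p_raw=float(omnibus[2]), p_adjusted=float(omnibus[2])))
    pairs = list(combinations(names, 2))
    m = len(pairs)
    for a, b in pairs:
        t_name, stat, p = pair_test(groups[a], groups[b])
        results.append(ComparisonResult(parameter=value, groups=(a, b),
                                        test=f"{t_name} + Bonferroni",
                                        statistic=float(stat), p_raw=float(p),
                                        p_adjusted=bonferroni(float(p), m)))
    return results


def _welch(a, b):
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return "Welch t", stat, p


def _mannwhitney(a, b):
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return "Mann-Whitney U", stat, p


def results_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results for CSV/markdown reporting."""
    return pd.DataFrame([{
        "parameter": r.parameter,
        "groups": " vs ".join(r.groups),
        "test": r.test,
        "statistic": r.statistic,
        "p_raw": r.p_raw,
        "p_adjusted": r.p_adjusted,
        "stars": r.stars,
    } for r in results])
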