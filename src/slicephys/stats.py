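"""The study's statistical procedures and small numeric utilities.

Two-group comparisons are routed by assumption checks: both samples must
pass Anderson-Darling *and* Shapiro-Wilk normality tests (p > alpha) and an
F-test for equality of variances to earn an unpaired two-sided t-test;
otherwise the Mann-Whitney U test is used.  Multiple comparisons use a
sequential rank-multiplication correction (multiply the most significant p
by N, the second by N-1, ...), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterError


@dataclass
class StatReport:
    test_name: str
    statistic: float
    p_value: float
    corrected_p: Optional[float] = None
    group_summaries: dict = field(default_factory=dict)
    assumptions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test_name, "statistic": self.statistic,
            "p": self.p_value, "corrected_p": self.corrected_p,
            "groups": self.group_summaries, "assumptions": self.assumptions,
        }


def _summary(x: np.ndarray) -> dict:
    return {"n": int(x.size), "mean": float(x.mean()),
            "sem": float(x.std(ddof=1) / np.sqrt(x.size))}


def select_two_group_test(a, b, alpha: float = 0.05) -> StatReport:
    """Assumption-routed unpaired comparison of two samples.

    t-test route requires p > alpha on Anderson-Darling and Shapiro-Wilk
    for *both* samples and on the variance F-test; any failure routes to
    Mann-Whitney U.  The report records the assumption p-values and the
    route taken.
    """
    from statsmodels.stats.diagnostic import normal_ad

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ParameterError("need at least 3 observations per group")

    assumptions = {}
    normal = True
    for name, x in (("a", a), ("b", b)):
        # samples with zero variance break the normality tests; route nonparametric
        if np.ptp(x) == 0:
            assumptions[f"shapiro_{name}"] = assumptions[f"ad_{name}"] = 0.0
            normal = False
            continue
        p_sw = sps.shapiro(x).pvalue
        p_ad = normal_ad(x)[1]
        assumptions[f"shapiro_{name}"] = float(p_sw)
        assumptions[f"ad_{name}"] = float(p_ad)
        if p_sw <= alpha or p_ad <= alpha:
            normal = False

    var_equal = False
    if normal:
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        F = v1 / v2 if v1 >= v2 else v2 / v1
        dfn = (a.size if v1 >= v2 else b.size) - 1
        dfd = (b.size if v1 >= v2 else a.size) - 1
        p_f = 2.0 * sps.f.sf(F, dfn, dfd)
        p_f = min(1.0, p_f)
        assumptions["f_test"] = float(p_f)
        var_equal = p_f > alpha

    if normal and var_equal:
        res = sps.ttest_ind(a, b)
        name = "unpaired t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
    return StatReport(test_name=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue),
                      group_summaries={"a": _summary(a), "b": _summary(b)},
                      assumptions=assumptions)


def holm_variant_correction(pvals) -> list:
    """Sequential rank-multiplication correction for N comparisons.

    The most significant p is multiplied by N, the second most significant
    by N-1, and so on; values are capped at 1 and returned in the original
    order.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    n = p.size
    corrected = np.empty_like(p)
    for rank, idx in enumerate(order):  # rank 0 = most significant
        corrected[idx] = min(1.0, p[idx] * (n - rank))
    return corrected.tolist()


def two_way_anova(data: pd.DataFrame, value: str, factor_a: str, factor_b: str,
                  posthoc: bool = True) -> dict:
    """Fixed-effects two-way ANOVA (main effects + interaction) with
    Bonferroni-adjusted pairwise post-hoc comparisons within levels.

    Requires every A x B cell to be non-empty.  Post-hoc compares levels of
    ``factor_a`` pairwise within each level of ``factor_b`` with unpaired
    t-tests, multiplying p by the number of comparisons.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    cells = df.groupby(["_a", "_b"], observed=True).size()
    n_a = df["_a"].nunique()
    n_b = df["_b"].nunique()
    if len(cells) < n_a * n_b:
        raise ParameterError("empty cells in the two-way design")

    if df["_y"].var(ddof=1) == 0:
        # degenerate: identical observations -> all F = 0
        zero = {"F": 0.0, "p": 1.0}
        return {"anova": {factor_a: zero, factor_b: zero, "interaction": zero},
                "posthoc": []}

    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {"anova": {
        factor_a: {"F": float(table.loc["C(_a)", "F"]),
                   "p": float(table.loc["C(_a)", "PR(>F)"])},
        factor_b: {"F": float(table.loc["C(_b)", "F"]),
                   "p": float(table.loc["C(_b)", "PR(>F)"])},
        "interaction": {"F": float(table.loc["C(_a):C(_b)", "F"]),
                        "p": float(table.loc["C(_a):C(_b)", "PR(>F)"])},
    }}
    posthoc_rows = []
    if posthoc:
        levels_a = sorted(df["_a"].unique())
        comparisons = []
        for bl in sorted(df["_b"].unique()):
            sub = df[df["_b"] == bl]
            for i in range(len(levels_a)):
                for j in range(i + 1, len(levels_a)):
                    x = sub[sub["_a"] == levels_a[i]]["_y"]
                    y = sub[sub["_a"] == levels_a[j]]["_y"]
                    p = sps.ttest_ind(x, y).pvalue
                    comparisons.append((bl, levels_a[i], levels_a[j], float(p)))
        m = len(comparisons)
        for bl, l1, l2, p in comparisons:
            posthoc_rows.append({"within": bl, "level_1": l1, "level_2": l2,
                                 "p": p, "p_bonferroni": min(1.0, p * m)})
    out["posthoc"] = posthoc_rows
    return out


def power_sample_size(effect_pct: float, sd_pct: float,
                      power: float = 0.80, alpha: float = 0.05,
                      n_max: int = 10_000) -> int:
    """Smallest n per group for a two-sided two-sample t-test.

    Cohen's d = effect / SD; power is evaluated exactly with the noncentral
    t distribution (ncp = d * sqrt(n/2), df = 2n - 2).
    """
    if sd_pct <= 0:
        raise ParameterError("sd must be positive")
    if not (0 < power < 1):
        raise ParameterError("power must be in (0, 1)")
    if effect_pct == 0:
        raise ParameterError("zero effect size: no finite sample size")
    d = abs(effect_pct) / sd_pct
    for n in range(2, n_max + 1):
        if t_test_power(d, n, alpha) >= power:
            return n
    raise ParameterError(f"no n <= {n_max} reaches the requested power")


def t_test_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact noncentral-t power of the two-sided two-sample t-test."""
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    tc = sps.t.ppf(1 - alpha / 2.0, df)
    return float(1 - sps.nct.cdf(tc, df, nc) + sps.nct.cdf(-tc, df, nc))


def monte_carlo_power(d: float, n_per_group: int, alpha: float = 0.05,
                      n_reps: int = 10_000, seed: int = 0) -> float:
    """Simulation oracle for t-test power (Gaussian samples, unit SD)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_reps, n_per_group))
    b = rng.normal(d, 1.0, size=(n_reps, n_per_group))
    p = sps.ttest_ind(a, b, axis=1).pvalue
    return float(np.mean(p < alpha))


def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object discrimination index, in [-100, 100].

    DI = 100 * (novel - familiar) / (novel + familiar): the difference of
    the exploration-time fractions, expressed as a percentage.
    """
    total = t_novel + t_familiar
    if total <= 0:
        raise ParameterError("total exploration time must be positive")
    return 100.0 * (t_novel - t_familiar) / total


def normalize_to_protein(analyte_pg: float, protein_mg: float) -> float:
    """ELISA analyte amount normalized to total protein, pg/mg."""
    if protein_mg <= 0:
        raise ParameterError("protein amount must be positive")
    return analyte_pg / protein_mg
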