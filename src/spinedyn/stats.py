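"""Group-comparison statistics: t-test, two-way ANOVA + Bonferroni, KS.

The comparisons mirror common practice in longitudinal spine-imaging
studies: unpaired pooled-variance Student t-tests between genotypes,
a two-factor (genotype × age) ANOVA with interaction followed by
Bonferroni-corrected genotype contrasts within each age using the ANOVA
error term, and the two-sample Kolmogorov–Smirnov test for pooled
morphometric distributions.  The unit of analysis is the dendrite for
rates/densities and the protrusion for pooled distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    df: float | tuple[int, int] | None
    p_value: float
    p_adjusted: Optional[float] = None
    degenerate: bool = False

    @property
    def stars(self) -> str:
        """Significance stars at the 0.05 / 0.01 / 0.001 levels."""
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"


def ttest_unpaired(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-tailed unpaired Student t-test (pooled variance by default).

    ``welch=True`` switches to the unequal-variance Welch test.  With
    zero pooled variance the statistic degenerates: equal means give
    t = 0, p = 1; unequal means give p -> 0, flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    if welch:
        res = scipy.stats.ttest_ind(x, y, equal_var=False)
        return TestResult(
            "welch_t", float(res.statistic), float(res.df), float(res.pvalue)
        )
    mx, my = x.mean(), y.mean()
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if mx == my:
            return TestResult("student_t", 0.0, df, 1.0)
        logger.warning("zero pooled variance with unequal means: degenerate t-test")
        t = float("inf") if mx > my else float("-inf")
        return TestResult("student_t", t, df, 0.0, degenerate=True)
    t = (mx - my) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return TestResult("student_t", float(t), df, float(p))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    two-tailed p-value uses the asymptotic Kolmogorov distribution with
    effective sample size ``n = nx*ny/(nx+ny)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / nx
    cdf_y = np.searchsorted(y, pooled, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = nx * ny / (nx + ny)
    p = float(scipy.special.kolmogorov(np.sqrt(ne) * d))
    return TestResult("ks_two_sample", d, (nx, ny), min(1.0, p))


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition with the pieces needed for contrasts."""

    effects: dict[str, TestResult]
    mse: float
    df_error: int
    anova_table: pd.DataFrame
    cell_counts: pd.DataFrame
    balanced: bool


def two_way_anova(
    values: Sequence[float],
    factor_genotype: Sequence,
    factor_age: Sequence,
) -> AnovaResult:
    """Two-factor ANOVA with interaction (genotype × age).

    Uses a Type I sum-of-squares decomposition on balanced data (where
    the types coincide) and falls back to Type II on unbalanced data,
    with a log notice.  Every cell must be nonempty.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": [str(g) for g in factor_genotype],
            "age": [str(a) for a in factor_age],
        }
    )
    if df["genotype"].nunique() < 2 or df["age"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby(["genotype", "age"]).size().unstack(fill_value=0)
    empty = [(g, a) for g in counts.index for a in counts.columns if counts.loc[g, a] == 0]
    if empty:
        raise ValueError(f"empty cell(s) in genotype x age design: {empty}")
    balanced = counts.values.min() == counts.values.max()
    if not balanced:
        logger.info("unbalanced design: using Type II sums of squares")

    model = smf.ols("value ~ C(genotype) * C(age)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1 if balanced else 2)

    df_error = int(table.loc["Residual", "df"])
    ss_error = float(table.loc["Residual", "sum_sq"])
    mse = ss_error / df_error if df_error > 0 else float("nan")
    # zero error variance up to float fuzz relative to the data scale
    scale = max(1.0, float(np.mean(np.square(df["value"]))))
    degenerate = not np.isfinite(mse) or mse <= 1e-12 * scale
    if degenerate:
        logger.warning("zero error mean square: ANOVA F statistics degenerate")

    name_map = {
        "C(genotype)": "genotype",
        "C(age)": "age",
        "C(genotype):C(age)": "interaction",
    }
    effects = {}
    for row_name, short in name_map.items():
        f = float(table.loc[row_name, "F"])
        p = float(table.loc[row_name, "PR(>F)"])
        effects[short] = TestResult(
            f"anova_{short}",
            f,
            (int(table.loc[row_name, "df"]), df_error),
            p,
            degenerate=degenerate,
        )
    return AnovaResult(effects, mse, df_error, table, counts, balanced)


def bonferroni_pairwise(
    values: Sequence[float],
    factor_genotype: Sequence,
    factor_age: Sequence,
    m: Optional[int] = None,
    anova: Optional[AnovaResult] = None,
) -> list[TestResult]:
    """Genotype contrasts within each age, Bonferroni-adjusted.

    Each contrast uses the ANOVA pooled error term:
    ``t = (mean1 - mean2) / sqrt(MSE * (1/n1 + 1/n2))`` on the residual
    degrees of freedom.  The family size ``m`` defaults to the number of
    ages (one contrast per age); adjusted p = min(1, p * m).
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": [str(g) for g in factor_genotype],
            "age": [str(a) for a in factor_age],
        }
    )
    genos = sorted(df["genotype"].unique())
    if len(genos) != 2:
        raise ValueError("pairwise genotype contrasts require exactly 2 genotypes")
    if anova is None:
        anova = two_way_anova(df["value"], df["genotype"], df["age"])
    ages = sorted(df["age"].unique())
    if m is None:
        m = len(ages)
    if m < 1:
        raise ValueError("family size m must be >= 1")

    results = []
    for age in ages:
        g1 = df[(df["age"] == age) & (df["genotype"] == genos[0])]["value"]
        g2 = df[(df["age"] == age) & (df["genotype"] == genos[1])]["value"]
        se = np.sqrt(anova.mse * (1.0 / len(g1) + 1.0 / len(g2)))
        if se == 0.0:
            t, p, degenerate = 0.0, 1.0, True
        else:
            t = float((g1.mean() - g2.mean()) / se)
            p = float(2.0 * scipy.stats.t.sf(abs(t), anova.df_error))
            degenerate = False
        results.append(
            TestResult(
                f"bonferroni_{genos[0]}_vs_{genos[1]}_age_{age}",
                t,
                anova.df_error,
                p,
                p_adjusted=min(1.0, p * m),
                degenerate=degenerate,
            )
        )
    return results


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across ≥2 groups (companion to the two-way model)."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    f, p = scipy.stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    k = len(groups)
    n = sum(len(g) for g in groups)
    return TestResult("anova_one_way", float(f), (k - 1, n - k), float(p))


def tukey_pairwise(
    values: Sequence[float], groups: Sequence
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons, as a tidy DataFrame."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(groups))
    return pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    """Tidy table of test results with significance stars."""
    rows = []
    for r in results:
        df_repr = (
            f"{r.df[0]},{r.df[1]}" if isinstance(r.df, tuple) else r.df
        )
        rows.append(
            {
                "comparison": r.name,
                "statistic": r.statistic,
                "df": df_repr,
                "p": r.p_value,
                "p_adjusted": r.p_adjusted if r.p_adjusted is not None else r.p_value,
                "significance": r.stars,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)
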