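"""Comparative statistics for the analysis: normality screen, omnibus and
pairwise non-parametric tests, rank-sum, t-test, correlations, regression.

All tests are two-sided. The omnibus/posthoc pair for comparing success
across initial behaviours is Kruskal-Wallis followed by Dunn's pairwise z
tests with Bonferroni adjustment over the pairs actually compared.
Standard tests delegate to scipy.stats; Dunn's test is computed here from
pooled ranks with the usual tie correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    statistic_name: str = "stat"
    df: float | None = None
    z: float | None = None
    adjusted_p: float | None = None
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray
    p: np.ndarray

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.variables.index(a), self.variables.index(b)
        return float(self.r[i, j]), float(self.p[i, j])


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    df: int
    p_value: float
    stderr: float = float("nan")


def _check_groups(groups, min_groups=2):
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for g in groups:
        if len(g) == 0:
            raise ValueError("every group must be non-empty")


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis rank test (non-parametric one-way ANOVA).

    H is tie-corrected; p comes from the chi-square approximation with
    k - 1 degrees of freedom. Identical pooled values give H = 0, p = 1.
    """
    _check_groups(groups)
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need a total of at least 3 observations")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):  # scipy raises on all-identical input
        return TestResult(method="Kruskal-Wallis", statistic=0.0, p_value=1.0,
                          statistic_name="H", df=len(groups) - 1)
    H, p = sps.kruskal(*groups)
    return TestResult(method="Kruskal-Wallis", statistic=float(H), p_value=float(p),
                      statistic_name="H", df=len(groups) - 1)


def dunn_pairwise(groups: dict[str, "np.ndarray | list"], adjust: str = "bonferroni"
                  ) -> list[TestResult]:
    """Dunn's post-hoc pairwise comparisons on pooled ranks.

    For groups a, b the statistic is

        z = (Rbar_a - Rbar_b) / sqrt(S * (1/n_a + 1/n_b)),
        S = (N (N+1) / 12) - T / (12 (N - 1)),

    where Rbar are mean pooled ranks and T = sum(t^3 - t) over tie groups.
    With ``adjust="bonferroni"`` each two-sided p is multiplied by the
    number of pairs compared, capped at 1.
    """
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(groups)
    _check_groups([groups[n] for n in names])
    sizes = {n: len(groups[n]) for n in names}
    pooled = np.concatenate([np.asarray(groups[n], dtype=float) for n in names])
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    pos = 0
    for n in names:
        mean_rank[n] = float(ranks[pos:pos + sizes[n]].mean())
        pos += sizes[n]
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    S = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        if S <= 0:  # all values tied: no evidence of any difference
            z, p = 0.0, 1.0
        else:
            se = math.sqrt(S * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        adj = min(1.0, m * p) if adjust == "bonferroni" else None
        results.append(TestResult(method="Dunn", statistic=float(z), p_value=float(p),
                                  statistic_name="z", z=float(z), adjusted_p=adj,
                                  groups=(a, b)))
    return results


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Reports W (the Mann-Whitney U of the first sample, as R's wilcox.test
    prints) plus the tie-corrected normal-approximation Z and its two-sided
    p-value. Identical samples give Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    U = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n1, n2 = len(x), len(y)
    N = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (N * (N - 1))
    var_u = n1 * n2 / 12.0 * (N + 1 - tie_term)
    mu_u = n1 * n2 / 2.0
    if var_u == 0:
        z, p = 0.0, 1.0
    else:
        z = (U - mu_u) / math.sqrt(var_u)
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(method="Wilcoxon rank-sum", statistic=U, p_value=float(p),
                      statistic_name="W", z=float(z))


def t_test_independent(x, y, equal_variance: bool = False) -> TestResult:
    """Independent-samples t-test; Welch by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(x, y, equal_var=equal_variance)
    if equal_variance:
        df = len(x) + len(y) - 2
    else:
        df = float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return TestResult(method="t-test (pooled)" if equal_variance else "t-test (Welch)",
                      statistic=t, p_value=p, statistic_name="t", df=df)


def ks_normality(x) -> TestResult:
    """One-sample Kolmogorov-Smirnov screen against N(mean(x), sd(x)).

    The reference normal uses the sample mean and sd; p comes from the
    asymptotic KS distribution. Constant samples are degenerate (sd = 0)
    and rejected.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: zero variance")
    D, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(method="Kolmogorov-Smirnov", statistic=float(D), p_value=float(p),
                      statistic_name="D")


def correlation_matrix(table, variables: list[str] | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlations with t-distributed p-values (df = n-2).

    ``table`` is a pandas DataFrame or 2-D array (rows = individuals,
    columns = variables). Each pair uses its pairwise-complete rows.
    Zero-variance columns yield NaN r/p for their pairs.
    """
    import pandas as pd

    df = pd.DataFrame(table, columns=variables) if not isinstance(table, pd.DataFrame) else table
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("need >= 3 rows and >= 2 columns")
    cols = list(df.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = df.iloc[:, [i, j]].dropna()
            a, b = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            if len(a) < 3 or a.std() == 0 or b.std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                rr, pp = sps.pearsonr(a, b)
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
    return CorrelationMatrix(variables=[str(c) for c in cols], r=r, p=p)


def linear_regression(x, y) -> RegressionFit:
    """Simple least-squares regression of y on x.

    Reports R^2, the adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2), df = n - 2
    and the two-sided p-value of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("x must not be constant")
    fit = sps.linregress(x, y)
    n = len(x)
    r2 = float(fit.rvalue**2)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r_squared=r2, adjusted_r_squared=adj, df=n - 2,
                         p_value=float(fit.pvalue), stderr=float(fit.stderr))
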