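"""Two-group and categorical statistics for cohort comparisons.

Continuous variables are routed by normality: Shapiro-Wilk on each group at
alpha = 0.05; when both groups pass, an independent two-sample t-test is
used and groups are described as mean (SD); otherwise the Mann-Whitney U
test is used and groups are described as median (IQR, Q3 - Q1, type-7
quantiles). All tests are two-tailed at alpha = 0.05; no multiple-testing
correction is applied by default (an optional Holm step is available for
families of p-values).

2x2 categorical tables use the Yates continuity-corrected chi-square by
default, Fisher's exact test when any expected count falls below 5, and
odds ratios with Woolf (log-normal) 95% confidence intervals, falling back
to the Haldane-Anscombe +0.5 correction when a cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "Descriptives",
    "descriptives",
    "MannWhitneyResult",
    "mann_whitney",
    "GroupComparison",
    "compare_groups",
    "ContingencyTable2x2",
    "Chi2Result",
    "chi2_yates",
    "OddsRatioResult",
    "odds_ratio",
    "fisher_exact",
    "spearman",
    "holm",
]

ALPHA = 0.05
_EXACT_MAX_N = 20  # exact Mann-Whitney enumeration up to this combined n (no ties)


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def descriptives(sample) -> Descriptives:
    """Mean/SD and median/IQR (type-7 quantiles, SD with ddof=1)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 1:
        raise ValueError("descriptives need at least one value")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # numpy default = type-7
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return Descriptives(n=int(x.size), mean=float(np.mean(x)), sd=sd,
                        median=float(med), q1=float(q1), q3=float(q3))


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    Exact permutation distribution when the combined sample size is <= 20
    and there are no ties; otherwise the midrank normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    if combined.size <= _EXACT_MAX_N and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(
        u=float(res.statistic), p=float(min(res.pvalue, 1.0)), method="asymptotic"
    )


@dataclass(frozen=True)
class GroupComparison:
    route: str | None  # "t_test" | "mann_whitney" | None (n too small)
    statistic: float
    p_value: float
    x_desc: Descriptives
    y_desc: Descriptives
    x_normal: bool | None = None
    y_normal: bool | None = None
    note: str = ""


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: Shapiro undefined, treat as non-normal
        return False
    return sps.shapiro(x).pvalue >= alpha


def compare_groups(x, y, alpha: float = ALPHA) -> GroupComparison:
    """Normality-routed two-group comparison.

    Shapiro-Wilk on each sample; both normal -> independent t-test,
    otherwise Mann-Whitney U. Groups of fewer than 3 values get
    descriptives only (Shapiro-Wilk minimum), with the test marked
    unavailable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = descriptives(x), descriptives(y)
    if min(x.size, y.size) < 3:
        return GroupComparison(
            route=None, statistic=float("nan"), p_value=float("nan"),
            x_desc=dx, y_desc=dy, note="test unavailable: group with n < 3",
        )
    nx, ny = _shapiro_normal(x, alpha), _shapiro_normal(y, alpha)
    if nx and ny:
        res = sps.ttest_ind(x, y)
        return GroupComparison(
            route="t_test", statistic=float(res.statistic), p_value=float(res.pvalue),
            x_desc=dx, y_desc=dy, x_normal=nx, y_normal=ny,
        )
    mw = mann_whitney(x, y)
    return GroupComparison(
        route="mann_whitney", statistic=mw.u, p_value=mw.p,
        x_desc=dx, y_desc=dy, x_normal=nx, y_normal=ny, note=f"mw_{mw.method}",
    )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d: rows = subgroup, columns = abnormal/normal."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("painful", "painless")
    col_labels: tuple[str, str] = ("abnormal", "normal")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("contingency counts must be nonnegative integers")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def expected(self) -> np.ndarray:
        t = self.counts
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / self.n


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p: float
    valid: bool
    note: str = ""


def chi2_yates(t: ContingencyTable2x2) -> Chi2Result:
    """Yates continuity-corrected chi-square on a 2x2 table (1 df).

    chi2 = n * (max(|ad - bc| - n/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d)).
    Undefined (flagged) when any margin is zero.
    """
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        return Chi2Result(float("nan"), float("nan"), valid=False, note="zero margin")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * num**2 / math.prod(margins)
    p = float(sps.chi2.sf(stat, df=1))
    return Chi2Result(statistic=float(stat), p=p, valid=True)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def odds_ratio(t: ContingencyTable2x2) -> OddsRatioResult:
    """Odds ratio ad/(bc) with a Woolf 95% confidence interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), and the result is flagged as corrected.
    """
    cells = [float(t.a), float(t.b), float(t.c), float(t.d)]
    corrected = any(v == 0 for v in cells)
    if corrected:
        cells = [v + 0.5 for v in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(sum(1.0 / v for v in cells))
    half = 1.959963984540054 * se
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - half),
        ci_high=math.exp(math.log(or_) + half),
        corrected=corrected,
    )


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p (sum of tables no more probable than observed)."""
    return float(sps.fisher_exact(t.counts, alternative="two-sided")[1])


def chi2_or_fisher(t: ContingencyTable2x2) -> dict:
    """Route a 2x2 table: Yates chi-square, or Fisher when any expected < 5."""
    if (t.expected < 5).any():
        return {"test": "fisher_exact", "statistic": float("nan"), "p": fisher_exact(t)}
    res = chi2_yates(t)
    return {"test": "chi2_yates", "statistic": res.statistic, "p": res.p}


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties); two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("spearman needs paired samples of length >= 4")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def holm(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
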