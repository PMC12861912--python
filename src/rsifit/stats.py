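"""Descriptive and inferential statistics for two-group cohort comparison.

Conventions (all fixed so that printed group summaries reproduce published
reference statistics exactly):

* unequal-variance (Welch) t-test, two-sided, with a moments-based overload
  so the test can be run from printed mean/SD/n summaries;
* Pearson chi-square on 2x2 tables without Yates continuity correction;
* Mann-Whitney U with midranks, tie-corrected normal approximation and no
  continuity correction;
* Wald odds-ratio interval on the log scale, no cell corrections;
* ICC(2,1): two-way random effects, absolute agreement, single measure;
* normality gate for automatic test selection: Shapiro-Wilk at alpha=0.05
  in each group;
* every p-value two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateTableError,
    InvalidInputError,
    UndefinedICCError,
)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | None = None


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts: (group1 positive, group1 negative, group2 positive,
    group2 negative)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise InvalidInputError("cell counts must be non-negative integers")
        if sum(cells) < 1:
            raise InvalidInputError("table must contain at least one count")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def welch_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> TestResult:
    """Welch t-test from group summaries (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidInputError("standard deviations must be positive")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult("welch_t", float(t), float(p), df=float(df))


def welch_t_samples(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch t-test from raw samples (computes moments, then delegates)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise InvalidInputError("each group needs n >= 2")
    return welch_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation.

    The statistic reported is the z-score for the first sample's U (no
    continuity correction); its sign is negative when the first sample
    tends to rank below the second.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise InvalidInputError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var == 0:
        raise InvalidInputError("all observations tied; U test undefined")
    z = (u1 - n1 * n2 / 2) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return TestResult("mann_whitney", float(z), float(p))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """The midrank U statistic for the first sample (ties credited 0.5)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


def pearson_chi2(table: TwoByTwoTable) -> TestResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    arr = table.as_array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal in 2x2 table")
    chi2, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult("pearson_chi2", float(chi2), float(p), df=float(df))


def odds_ratio_2x2(table: TwoByTwoTable) -> ORResult:
    """Cross-product odds ratio with Wald 95% CI (requires all cells > 0)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        raise DegenerateTableError(
            "zero cell: Wald odds-ratio interval undefined "
            "(no continuity correction is applied silently)"
        )
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_) / se
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * 1.959963984540054 * se)
    p = 2 * sps.norm.sf(abs(z))
    return ORResult(float(or_), float(lo), float(hi), float(z), float(p))


def icc_agreement(
    reader1: Sequence[float], reader2: Sequence[float]
) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the standard two-way ANOVA decomposition with subjects as
    rows and the two readers as columns.
    """
    x = np.column_stack(
        [np.asarray(reader1, float), np.asarray(reader2, float)]
    )
    n, k = x.shape
    if n < 3:
        raise InvalidInputError("need at least 3 subjects")
    grand = x.mean()
    if np.allclose(x, grand):
        raise UndefinedICCError("zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedICCError("degenerate variance decomposition")
    return float((msr - mse) / denom)


def select_test(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Shapiro-Wilk gate: Welch t when both groups look normal, otherwise
    Mann-Whitney.  The chosen branch is visible in the result ``name``."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise InvalidInputError("need at least 3 observations per group")
    normal = (
        sps.shapiro(x).pvalue > alpha and sps.shapiro(y).pvalue > alpha
    )
    return welch_t_samples(x, y) if normal else mann_whitney(x, y)


# --------------------------------------------------------------------------
# descriptive report


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Two-group descriptive comparison of a cohort table.

    Continuous variables are routed through the Shapiro-Wilk gate and
    summarised as mean +/- SD (t branch) or median (IQR) (U branch);
    binary variables use the chi-square test.  Fractions are reported on
    the x1e-2 scale and ADC in 1e-3 mm^2/s.
    """
    scc = cohort[cohort["group"] == "SCC"]
    ac = cohort[cohort["group"] == "AC"]
    scale = {"f1": 100.0, "f2": 100.0, "f3": 100.0}
    rows = []
    continuous = ["age", "diameter_cm", "f1", "f2", "f3", "adc", "suvmax"]
    for var in continuous:
        s = scc[var].to_numpy() * scale.get(var, 1.0)
        a = ac[var].to_numpy() * scale.get(var, 1.0)
        res = select_test(s, a)
        if res.name == "welch_t":
            s_sum = f"{_fmt(s.mean())} ± {_fmt(s.std(ddof=1))}"
            a_sum = f"{_fmt(a.mean())} ± {_fmt(a.std(ddof=1))}"
        else:
            sq = np.percentile(s, [25, 50, 75])
            aq = np.percentile(a, [25, 50, 75])
            s_sum = f"{_fmt(sq[1])} ({_fmt(sq[0])}, {_fmt(sq[2])})"
            a_sum = f"{_fmt(aq[1])} ({_fmt(aq[0])}, {_fmt(aq[2])})"
        rows.append((var, s_sum, a_sum, res.name, res.statistic, res.p_value))
    for var in ("sex_male", "smoking"):
        t = TwoByTwoTable(
            int(scc[var].sum()), int((1 - scc[var]).sum()),
            int(ac[var].sum()), int((1 - ac[var]).sum()),
        )
        res = pearson_chi2(t)
        rows.append(
            (
                var,
                f"{t.a}/{t.a + t.b} ({100 * t.a / (t.a + t.b):.2f}%)",
                f"{t.c}/{t.c + t.d} ({100 * t.c / (t.c + t.d):.2f}%)",
                res.name, res.statistic, res.p_value,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["variable", f"SCC (n={len(scc)})", f"AC (n={len(ac)})",
                 "test", "statistic", "p_value"],
    )
    out["statistic"] = out["statistic"].round(3)
    return out
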