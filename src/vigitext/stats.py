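"""Descriptive and inferential statistics for adverse-event frequencies.

Covers the comparative toolkit used in registry-vs-self-report studies:
per-class frequency tables, prevalence ratios between two samples, Fisher
exact tests on 2x2 tables, Mann-Whitney U comparisons of per-report AE
counts, Shapiro-Wilk normality checks, ordinary least squares of AE count
on age, and Pearson/Spearman correlations of frequency vectors.

All tests are two-sided.  No multiple-testing correction is applied — the
toolkit reports raw p-values and leaves adjustment policy to the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .labels import SYMPTOMS, stack_labels


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyTable:
    """Per-category counts with an explicit denominator."""

    categories: tuple[str, ...]
    counts: np.ndarray
    denominator: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if counts.min(initial=0) < 0 or counts.max(initial=0) > self.denominator:
            raise ValueError("counts must lie in [0, denominator]")
        if len(self.categories) != counts.size:
            raise ValueError("categories and counts length mismatch")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def percentages(self) -> np.ndarray:
        return self.counts / self.denominator * 100.0

    def count(self, category: str) -> int:
        return int(self.counts[self.categories.index(category)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "count": self.counts,
                "denominator": self.denominator,
                "percent": np.round(self.percentages, 2),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrequencyTable":
        df = pd.read_csv(path, comment="#")
        denom = int(df["denominator"].iloc[0])
        return cls(tuple(df["category"]), df["count"].to_numpy(int), denom)


def frequency_table(
    labelsets: Sequence[Sequence[bool]], denominator: int
) -> FrequencyTable:
    """Count positives per symptom class over label sets.

    ``denominator`` is explicit (it may exceed the number of contributing
    label sets, e.g. when the population includes reports with no AE).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    mat = stack_labels(labelsets)
    if denominator < mat.shape[0]:
        raise ValueError("denominator smaller than number of label sets")
    return FrequencyTable(SYMPTOMS, mat.sum(axis=0).astype(int), denominator)


# ---------------------------------------------------------------------------
# Two-sample frequency comparisons
# ---------------------------------------------------------------------------

def prevalence_ratio(count_a: int, n_a: int, count_b: int, n_b: int) -> float:
    """(count_a/n_a) / (count_b/n_b); ``inf`` when the reference rate is 0."""
    if n_a <= 0 or n_b <= 0:
        raise ValueError("denominators must be positive")
    if count_b == 0:
        return math.inf
    return (count_a / n_a) / (count_b / n_b)


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Classical cross-product odds ratio ad/bc (``inf`` if bc = 0)."""
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all margin-preserving tables as or
    less probable than the observed one.  An all-zero table gives p = 1 by
    convention.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Mann-Whitney comparison of AE counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of per-report AE counts."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    quartiles_a: tuple[float, float, float]
    quartiles_b: tuple[float, float, float]
    ratio_of_means: float
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m, s, q in (
            (self.group_a, self.mean_a, self.sd_a, self.quartiles_a),
            (self.group_b, self.mean_b, self.sd_b, self.quartiles_b),
        ):
            rows.append(
                {
                    "group": name,
                    "mean": m,
                    "sd": s,
                    "q1": q[0],
                    "q2": q[1],
                    "q3": q[2],
                    "ratio_of_means": self.ratio_of_means,
                    "U": self.u_statistic,
                    "p": self.p_value,
                    "method": self.method,
                }
            )
        return pd.DataFrame(rows)


_EXACT_LIMIT = 200_000  # max number of enumerated group assignments


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by exhaustive enumeration.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes and compares |U - E[U]| against the observed deviation.
    Handles ties exactly (ranks are midranks of the pooled sample, which
    are invariant across assignments).
    """
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def mann_whitney_compare(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison with descriptive summaries.

    Small samples (when full enumeration is tractable) use the exact
    tie-aware permutation distribution of U; larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(counts_a, dtype=float)
    y = np.asarray(counts_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")

    if math.comb(x.size + y.size, x.size) <= _EXACT_LIMIT:
        u, p = _exact_mw_p(x, y)
        method = "exact"
    else:
        u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(u), float(p)
        method = "asymptotic"

    qa = tuple(np.percentile(x, [25, 50, 75]))
    qb = tuple(np.percentile(y, [25, 50, 75]))
    mean_b = float(y.mean())
    ratio = float(x.mean() / mean_b) if mean_b != 0 else math.inf
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(x.mean()),
        mean_b=mean_b,
        sd_a=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        sd_b=float(y.std(ddof=1)) if y.size > 1 else 0.0,
        quartiles_a=qa,
        quartiles_b=qb,
        ratio_of_means=ratio,
        u_statistic=u,
        p_value=min(1.0, p),
        method=method,
    )


# ---------------------------------------------------------------------------
# Normality, regression, correlation
# ---------------------------------------------------------------------------

def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (n in [3, 5000])."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of per-report AE count on age.

    ``slope`` is the magnitude of the change per year; ``direction`` is
    -1 for a decline with age, +1 for an increase.
    """

    slope: float
    direction: int
    intercept: float
    slope_se: float
    p_value: float
    n: int

    @property
    def signed_slope(self) -> float:
        return self.direction * self.slope


def fit_age_slope(
    ages: Sequence[float], ae_counts: Sequence[float], min_age: float = 18
) -> RegressionFit:
    """OLS of AE count on age over reports with age >= ``min_age``."""
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(ae_counts, dtype=float)
    if ages.shape != counts.shape:
        raise ValueError("ages and ae_counts must have equal length")
    keep = ages >= min_age
    ages, counts = ages[keep], counts[keep]
    if ages.size < 3:
        raise ValueError("need at least 3 records after the age filter")
    if np.ptp(ages) == 0:
        raise ValueError("no age variance after filtering")
    X = sm.add_constant(ages)
    fit = sm.OLS(counts, X).fit()
    beta = float(fit.params[1])
    return RegressionFit(
        slope=abs(beta),
        direction=-1 if beta < 0 else 1,
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(ages.size),
    )


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def format_p(p: float) -> str:
    """Display convention: 3 decimals, floored at '<.001'."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"
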