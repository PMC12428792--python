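"""Contingency-table inference and numeric descriptives.

Implements the statistical battery of the cohort analysis: Pearson chi-square
with expected-cell diagnostics, Monte Carlo simulated p-values from random
tables with both margins fixed (the Patefield sampler, the convention SPSS
follows when expected cell counts fall below 5), Cramer's V with a percentile
bootstrap confidence interval, exact (Clopper-Pearson) binomial proportion
intervals, t-based confidence intervals for means, and the tie-corrected
Kruskal-Wallis test with group mean ranks.

Scientific conventions
----------------------
* The Monte Carlo p-value uses the positively biased estimator
  ``(1 + #{chi2* >= chi2_obs}) / (1 + B)`` so a simulated p is never zero,
  and reports a normal-approximation binomial interval (99% by default,
  matching the convention of the source software).
* Cramer's V uses the textbook denominator ``n * (min(r, c) - 1)``.
* Rows or columns with a zero margin are dropped (with a warning) before
  testing rather than producing 0/0 expected counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .cohort import ContingencyTable

__all__ = [
    "ChiSquareResult",
    "MonteCarloP",
    "ProportionCI",
    "MeanSummary",
    "KruskalWallisResult",
    "DegenerateTableError",
    "pearson_chi_square",
    "monte_carlo_p",
    "cramers_v",
    "bootstrap_v_ci",
    "clopper_pearson",
    "summarize_numeric",
    "t_mean_ci",
    "kruskal_wallis",
    "odds_ratio_woolf",
]


class DegenerateTableError(ValueError):
    """Fewer than two non-empty rows or columns remain after margin pruning."""


@dataclass(frozen=True)
class MonteCarloP:
    """Monte Carlo estimate of a chi-square p-value under fixed margins."""

    p_hat: float
    ci_low: float
    ci_high: float
    level: float
    replicates: int
    seed: int


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test with effect size and cell diagnostics."""

    statistic: float
    df: int
    p_asymptotic: float
    min_expected: float
    pct_cells_expected_lt5: float
    cramers_v: float
    n: int
    shape: tuple[int, int]
    v_ci: tuple[float, float] | None = None
    monte_carlo: MonteCarloP | None = None


@dataclass(frozen=True)
class ProportionCI:
    """Exact binomial proportion estimate with confidence interval."""

    successes: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    level: float


@dataclass(frozen=True)
class MeanSummary:
    """Descriptives for a numeric variable with a t-based CI for the mean."""

    n: int
    mean: float
    sd: float
    se: float
    ci_t: tuple[float, float]
    trimmed_mean_5pct: float
    median: float
    skewness: float
    skewness_defined: bool = True


@dataclass(frozen=True)
class KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with per-group mean ranks."""

    H: float
    df: int
    p: float
    mean_ranks: dict[str, float]
    all_tied: bool = False


def _pruned_array(table: ContingencyTable) -> np.ndarray:
    """Counts with zero-margin rows/columns removed (warning if any dropped)."""
    arr = table.to_array()
    keep_rows = arr.sum(axis=1) > 0
    keep_cols = arr.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn(
            f"dropping {int((~keep_rows).sum())} zero row(s) and "
            f"{int((~keep_cols).sum())} zero column(s) from "
            f"{table.row_var} x {table.col_var} before testing",
            stacklevel=3,
        )
    arr = arr[keep_rows][:, keep_cols]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateTableError(
            f"{table.row_var} x {table.col_var}: fewer than 2 non-empty rows/columns"
        )
    return arr


def cramers_v(statistic: float, n: int, r: int, c: int) -> float:
    """Cramer's V effect size: sqrt(chi2 / (n * (min(r, c) - 1))), clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if r < 2 or c < 2:
        raise ValueError("r and c must be at least 2")
    v = float(np.sqrt(statistic / (n * (min(r, c) - 1))))
    return min(max(v, 0.0), 1.0)


def pearson_chi_square(
    table: ContingencyTable,
    mc_replicates: int | None = None,
    seed: int | None = None,
    mc_level: float = 0.99,
) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction is applied (the study's convention, also for
    2 x 2 tables).  If ``mc_replicates`` is given, a Monte Carlo simulated
    p-value with both margins fixed is attached.
    """
    arr = _pruned_array(table)
    chi2 = sps.chi2_contingency(arr, correction=False)
    expected = chi2.expected_freq
    r, c = arr.shape
    result = ChiSquareResult(
        statistic=float(chi2.statistic),
        df=int(chi2.dof),
        p_asymptotic=float(chi2.pvalue),
        min_expected=float(expected.min()),
        pct_cells_expected_lt5=float(100.0 * (expected < 5).mean()),
        cramers_v=cramers_v(float(chi2.statistic), int(arr.sum()), r, c),
        n=int(arr.sum()),
        shape=(r, c),
        monte_carlo=(
            monte_carlo_p(table, B=mc_replicates, seed=seed or 0, level=mc_level)
            if mc_replicates
            else None
        ),
    )
    return result


def _chi_square_statistics(tables: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Pearson statistic for a (B, r, c) stack of tables sharing one expected matrix."""
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (tables - expected) ** 2 / expected
    return np.nansum(contrib, axis=(-2, -1))


def monte_carlo_p(
    table: ContingencyTable,
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.99,
) -> MonteCarloP:
    """Monte Carlo simulated chi-square p-value with both margins fixed.

    Draws ``B`` random tables from the null distribution given the observed
    row and column margins (Patefield's algorithm) and estimates
    ``p = (1 + #{chi2* >= chi2_obs}) / (1 + B)``, with a normal-approximation
    binomial confidence interval at ``level``.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    arr = _pruned_array(table)
    n = arr.sum()
    row_m, col_m = arr.sum(axis=1), arr.sum(axis=0)
    expected = np.outer(row_m, col_m) / n
    observed_stat = float(((arr - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(row_m, col_m)
    sims = sampler.rvs(B, random_state=rng)
    stats_b = _chi_square_statistics(np.asarray(sims, dtype=float), expected)
    exceed = int((stats_b >= observed_stat - 1e-9).sum())  # tolerate fp ties
    p_hat = (1 + exceed) / (1 + B)
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p_hat * (1 - p_hat) / B)
    return MonteCarloP(
        p_hat=float(p_hat),
        ci_low=float(max(0.0, p_hat - half)),
        ci_high=float(min(1.0, p_hat + half)),
        level=level,
        replicates=B,
        seed=seed,
    )


def bootstrap_v_ci(
    pairs: Sequence[tuple[str, str]],
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for Cramer's V from (row, col) observations.

    Records are resampled with replacement at fixed n.  A resample that loses
    a whole category is recomputed on its collapsed table (categories present
    in the resample only); resamples collapsing below 2 x 2 contribute V = 0.
    """
    pairs = list(pairs)
    n = len(pairs)
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    if len(np.unique(rows)) < 2 or len(np.unique(cols)) < 2:
        raise ValueError("need at least 2 distinct row and column labels")
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        r_codes, _ = _codes(rows[idx])
        c_codes, _ = _codes(cols[idx])
        r_lev, c_lev = r_codes.max() + 1, c_codes.max() + 1
        if r_lev < 2 or c_lev < 2:
            values[b] = 0.0
            continue
        counts = np.zeros((r_lev, c_lev), dtype=int)
        np.add.at(counts, (r_codes, c_codes), 1)
        expected = np.outer(counts.sum(1), counts.sum(0)) / n
        stat = float(((counts - expected) ** 2 / expected).sum())
        values[b] = cramers_v(stat, n, r_lev, c_lev)
    alpha = 1 - level
    low, high = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(low), float(high)


def _codes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniques, codes = np.unique(labels, return_inverse=True)
    return codes, uniques


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact (beta-quantile) binomial confidence interval for a proportion."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1 - level, method="beta")
    low = 0.0 if k == 0 else float(low)
    high = 1.0 if k == n else float(high)
    return ProportionCI(
        successes=k, n=n, p_hat=k / n, ci_low=low, ci_high=high, level=level
    )


def t_mean_ci(
    mean: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """t-based CI for a mean from summary statistics: mean +/- t * sd / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = sps.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def summarize_numeric(values: Sequence[float], level: float = 0.95) -> MeanSummary:
    """Descriptives for a numeric sample.

    Reports mean, sample SD, SE, the t-based CI, the 5% trimmed mean (dropping
    ``floor(0.05 n)`` observations from each tail), the median, and the
    adjusted Fisher-Pearson skewness.  A constant sample yields a degenerate
    CI and skewness reported as 0 with ``skewness_defined=False``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(n)
    ci = t_mean_ci(mean, sd, n, level)
    trimmed = float(sps.trim_mean(x, 0.05))
    if sd == 0 or n < 3:
        skew, defined = 0.0, False
    else:
        skew, defined = float(sps.skew(x, bias=False)), True
    return MeanSummary(
        n=n,
        mean=mean,
        sd=sd,
        se=float(se),
        ci_t=ci,
        trimmed_mean_5pct=trimmed,
        median=float(np.median(x)),
        skewness=skew,
        skewness_defined=defined,
    )


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str]
) -> KruskalWallisResult:
    """Kruskal-Wallis H test with midrank ties and per-group mean ranks.

    If every value is identical the statistic is reported as 0 with
    ``all_tied=True`` rather than failing.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if x.size != g.size:
        raise ValueError("values and groups must have equal length")
    labels = list(dict.fromkeys(g.tolist()))  # first-appearance order
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    ranks = sps.rankdata(x)
    mean_ranks = {lab: float(ranks[g == lab].mean()) for lab in labels}
    samples = [x[g == lab] for lab in labels]
    if np.all(x == x[0]):
        return KruskalWallisResult(
            H=0.0, df=len(labels) - 1, p=1.0, mean_ranks=mean_ranks, all_tied=True
        )
    H, p = sps.kruskal(*samples)
    return KruskalWallisResult(
        H=float(H), df=len(labels) - 1, p=float(p), mean_ranks=mean_ranks
    )


def odds_ratio_woolf(
    table: ContingencyTable, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Odds ratio with a Woolf (log-normal) CI for a 2 x 2 table (convenience).

    Applies the Haldane-Anscombe 0.5 correction when any cell is zero.
    """
    arr = table.to_array().astype(float)
    if arr.shape != (2, 2):
        raise ValueError("odds ratio requires a 2 x 2 table")
    if (arr == 0).any():
        arr = arr + 0.5
    (a, b), (c, d) = arr
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.5 + level / 2)
    return float(or_), (float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se)))
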