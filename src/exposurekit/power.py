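"""Chi-square power analysis in the noncentral asymptotic framework.

Power for a chi-square test of association with effect size w is
``P(X > c)`` where ``X ~ noncentral chi-square(df, lambda = n * w**2)`` and
``c`` is the central chi-square ``1 - alpha`` quantile with the same df.
``required_n`` inverts this for the smallest integer n reaching a target
power.  This is the same framework G*Power uses for its "Chi-square tests -
Goodness-of-fit tests, contingency tables" family.

Note on degrees of freedom: the published sample-size statement (n = 126 at
w = 0.25, alpha = 0.05, power = 0.80) is reproduced with df = 1
(lambda = 7.849 => n = 125.6 -> 126); a four-group comparison at df = 3 would
require 175.  df is therefore an explicit, mandatory parameter here.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

__all__ = ["PowerSpec", "achieved_power", "required_n"]


def _validate(w: float, alpha: float, df: int) -> None:
    if w < 0:
        raise ValueError("effect size w must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be at least 1")


def achieved_power(n: int, w: float, alpha: float, df: int) -> float:
    """Power of the chi-square test at sample size n and effect size w."""
    _validate(w, alpha, df)
    if n < 1:
        raise ValueError("n must be at least 1")
    crit = sps.chi2.ppf(1 - alpha, df)
    if w == 0:
        return float(alpha)
    return float(sps.ncx2.sf(crit, df, n * w * w))


def required_n(w: float, alpha: float, power: float, df: int) -> int:
    """Smallest integer n whose achieved power reaches the target.

    Monotone in each argument; raises for an unattainable target (w = 0).
    """
    _validate(w, alpha, df)
    if not alpha < power < 1:
        raise ValueError("need alpha < power < 1")
    if w == 0:
        raise ValueError("target power is unattainable at w = 0")
    lo, hi = 1, 2
    while achieved_power(hi, w, alpha, df) < power:
        lo, hi = hi, hi * 2
        if hi > 10**9:
            raise ValueError("required n exceeds 1e9; check parameters")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if achieved_power(mid, w, alpha, df) >= power:
            hi = mid
        else:
            lo = mid
    return hi if achieved_power(lo, w, alpha, df) < power else lo


@dataclass(frozen=True)
class PowerSpec:
    """A power-analysis design point with its derived quantities."""

    w: float
    alpha: float
    power: float
    df: int
    n_required: int
    noncentrality: float

    @classmethod
    def solve(cls, w: float, alpha: float, power: float, df: int) -> "PowerSpec":
        n = required_n(w, alpha, power, df)
        return cls(
            w=w, alpha=alpha, power=power, df=df,
            n_required=n, noncentrality=n * w * w,
        )
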