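"""Chi-square goodness-of-fit against expected category percentages.

The statistic is chi2 = sum_i (O_i - E_i)^2 / E_i with expected counts
E_i = p_i * sum(O), where p_i are the expected percentages.  Percentages
are used exactly as given (e.g. 33.3/33.4/33.3 summing to 100.0, or
60.14/14.55/25.3 summing to 99.99): sums within 0.002 of 1 are accepted
without renormalization, which is required to reproduce printed
worked-example statistics.  Degrees of freedom are N - 1 and
significance is decided against the upper-tail critical value of the
chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["ChiSquareResult", "chi_square", "chi2_critical"]

_PCT_TOL = 0.002


@dataclass(frozen=True)
class ChiSquareResult:
    observed: tuple[float, ...]
    expected_pct: tuple[float, ...]
    expected: tuple[float, ...]
    statistic: float
    df: int
    alpha: float
    critical_value: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.statistic >= self.critical_value


def _normalize_pct(expected_pct: Sequence[float]) -> np.ndarray:
    p = np.asarray(expected_pct, dtype=float)
    total = p.sum()
    if abs(total - 100.0) <= 100.0 * _PCT_TOL:
        p = p / 100.0  # given in percent
        total = p.sum()
    if abs(total - 1.0) > _PCT_TOL:
        raise ValueError(f"expected percentages sum to {total:.6f}, not 1 (±{_PCT_TOL})")
    return p


def chi_square(
    observed: Sequence[float],
    expected_pct: Sequence[float],
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Goodness-of-fit test of observed counts against expected percentages.

    ``expected_pct`` may be given as fractions (0.333, ...) or percents
    (33.3, ...); they are used as printed, not renormalized.  Requires at
    least two categories and strictly positive expected counts.
    """
    o = np.asarray(observed, dtype=float)
    if o.ndim != 1 or len(o) < 2:
        raise ValueError("need at least two categories of observed counts")
    p = _normalize_pct(expected_pct)
    if len(p) != len(o):
        raise ValueError("observed and expected have different category counts")
    e = p * o.sum()
    if np.any(e <= 0):
        raise ValueError("all expected counts must be > 0")
    stat = float(((o - e) ** 2 / e).sum())
    df = len(o) - 1
    crit = chi2_critical(df, alpha)
    return ChiSquareResult(
        observed=tuple(o),
        expected_pct=tuple(p),
        expected=tuple(e),
        statistic=stat,
        df=df,
        alpha=alpha,
        critical_value=crit,
        p_value=float(sps.chi2.sf(stat, df)),
    )


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-tail alpha quantile of the chi-square distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.chi2.ppf(1.0 - alpha, df))
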