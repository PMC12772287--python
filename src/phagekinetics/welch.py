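"""Welch's two-sample t-test from summary statistics.

The comparison operates on (mean, SD, n) triples alone — the same interface
as classic summary-statistics t-test utilities — because the quantities being
compared here (fitted rate constants, burst sizes) arrive as point estimates
with standard errors rather than as raw samples.

t = (m1 - m2) / sqrt(s1²/n1 + s2²/n2), with Welch–Satterthwaite degrees of
freedom (not rounded to an integer) and a two-sided p from the Student-t
survival function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import DegenerateVarianceError, InsufficientDataError

__all__ = ["WelchResult", "welch_tsum"]


@dataclass(frozen=True)
class WelchResult:
    """Result of a Welch two-sample t-test computed from summary statistics."""

    t_statistic: float
    df: float
    p_two_sided: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "n1": self.n1,
            "n2": self.n2,
        }


def welch_tsum(m1: float, s1: float, n1: int,
               m2: float, s2: float, n2: int) -> WelchResult:
    """Welch's modified two-sample t-test from summary statistics.

    Parameters
    ----------
    m1, m2 : group means.
    s1, s2 : group standard deviations (>= 0, not both 0).
    n1, n2 : group sizes (>= 2).

    Raises
    ------
    InsufficientDataError
        If either n < 2.
    DegenerateVarianceError
        If both SDs are exactly zero (t undefined; no p is fabricated).
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"Welch t-test needs n >= 2 in each group (got {n1}, {n2})")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        raise DegenerateVarianceError(
            "both groups have zero SD; the t statistic is undefined")

    v1 = s1 * s1 / n1
    v2 = s2 * s2 / n2
    se = math.sqrt(v1 + v2)
    t = (m1 - m2) / se
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t_statistic=t, df=df, p_two_sided=min(p, 1.0),
                       n1=int(n1), n2=int(n2))
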