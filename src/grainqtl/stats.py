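"""Segregation-ratio and phenotype-comparison statistics.

Two small tests recur in F2 cross analysis: a chi-squared goodness-of-fit
test of the observed phenotype-class counts against a Mendelian ratio
(3:1 for a monogenic recessive trait), and Welch's unequal-variance t-test
comparing a quantitative phenotype between two groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SegregationTestResult",
    "WelchTestResult",
    "chi_square_segregation",
    "welch_t_test",
]


@dataclass(frozen=True)
class SegregationTestResult:
    """Goodness-of-fit of two observed class counts to an expected ratio."""

    n_dominant: int
    n_recessive: int
    ratio: tuple[float, float]
    chi2: float
    df: int
    p_value: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __str__(self) -> str:  # 4-decimal text form; full precision in JSON
        return (
            f"observed {self.n_dominant}:{self.n_recessive} vs "
            f"{self.ratio[0]:g}:{self.ratio[1]:g} -> "
            f"chi2 = {self.chi2:.4f}, df = {self.df}, p = {self.p_value:.4f}"
        )


@dataclass(frozen=True)
class WelchTestResult:
    t: float
    df: float
    p_value: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def chi_square_segregation(
    n_dominant: int,
    n_recessive: int,
    ratio: tuple[float, float] = (3, 1),
) -> SegregationTestResult:
    """Pearson chi-squared test of a two-class segregation ratio.

    No continuity correction is applied, matching the convention for
    Mendelian ratio tests. Expected counts are ``total * ratio_share``;
    the p-value is the upper tail of the chi-squared distribution with
    ``df = 1``.

    Parameters
    ----------
    n_dominant, n_recessive
        Observed counts of the dominant-phenotype and recessive-phenotype
        classes.
    ratio
        Expected ratio ``(dominant, recessive)``; scaling the tuple does
        not change the result, so ``(3, 1)`` and ``(6, 2)`` are equivalent.
    """
    if n_dominant < 0 or n_recessive < 0:
        raise ValueError("counts must be non-negative")
    total = n_dominant + n_recessive
    if total == 0:
        raise ValueError("at least one observation required")
    if min(ratio) <= 0:
        raise ValueError("ratio components must be positive")
    shares = np.asarray(ratio, dtype=float)
    shares = shares / shares.sum()
    expected = total * shares
    observed = np.array([n_dominant, n_recessive], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return SegregationTestResult(
        n_dominant=int(n_dominant),
        n_recessive=int(n_recessive),
        ratio=(float(ratio[0]), float(ratio[1])),
        chi2=chi2,
        df=df,
        p_value=p,
    )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchTestResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Computed from the standard formulas,

        t  = (mean(x) - mean(y)) / sqrt(sx^2/nx + sy^2/ny)
        df = (sx^2/nx + sy^2/ny)^2 /
             ((sx^2/nx)^2/(nx-1) + (sy^2/ny)^2/(ny-1))

    with sample variances ``s^2`` using the n-1 denominator; the p-value is
    two-sided from Student's t distribution with the (fractional) df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return WelchTestResult(t=0.0, df=float(x.size + y.size - 2), p_value=1.0)
        raise ValueError("both samples degenerate with unequal means")
    se2x = vx / x.size
    se2y = vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2x + se2y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchTestResult(t=float(t), df=float(df), p_value=p)
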