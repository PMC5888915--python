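"""Segregation and marker-association chi-square statistics.

Goodness-of-fit of a two-class phenotype or marker segregation against an
expected ratio (default 1:1), with one degree of freedom.  Yates' continuity
correction is supported as an option because published segregation tests mix
corrected and uncorrected statistics; :func:`chi_square_both` computes both
so a reported value can be matched to its convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as _stats

__all__ = ["SegregationTest", "chi_square_ratio", "chi_square_both"]


@dataclass(frozen=True)
class SegregationTest:
    observed: tuple[int, int]
    expected: tuple[float, float]
    ratio: tuple[float, float]
    yates: bool
    statistic: float
    dof: int
    p: float


def chi_square_ratio(
    observed: tuple[int, int],
    ratio: tuple[float, float] = (1.0, 1.0),
    yates: bool = False,
) -> SegregationTest:
    """Chi-square goodness of fit of two observed counts to a ratio.

    statistic = sum((|O - E| - c)^2 / E) with c = 0.5 under Yates'
    correction (capped at |O - E| so tiny deviations cannot contribute
    negatively), else c = 0; p from chi-square with 1 dof.
    """
    a, b = observed
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError("total count must be positive")
    w1, w2 = ratio
    if w1 <= 0 or w2 <= 0:
        raise ValueError("ratio weights must be positive")
    e1 = total * w1 / (w1 + w2)
    e2 = total * w2 / (w1 + w2)
    statistic = 0.0
    for o, e in ((a, e1), (b, e2)):
        dev = abs(o - e)
        c = min(0.5, dev) if yates else 0.0
        statistic += (dev - c) ** 2 / e
    p = float(_stats.chi2.sf(statistic, df=1))
    return SegregationTest(
        observed=(a, b),
        expected=(e1, e2),
        ratio=(float(w1), float(w2)),
        yates=yates,
        statistic=statistic,
        dof=1,
        p=p,
    )


def chi_square_both(
    observed: tuple[int, int], ratio: tuple[float, float] = (1.0, 1.0)
) -> tuple[SegregationTest, SegregationTest]:
    """(uncorrected, Yates-corrected) tests for the same counts."""
    return (
        chi_square_ratio(observed, ratio, yates=False),
        chi_square_ratio(observed, ratio, yates=True),
    )
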