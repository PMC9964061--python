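"""Chi-square goodness-of-fit tests for Mendelian segregation ratios.

A monogenic recessive trait segregates 3:1 (wild-type:mutant) in an F2
family, or in the selfed progeny of a heterozygote.  The test compares
observed class counts against that expectation with a 1-df Pearson
chi-square statistic (no continuity correction) and reports the
one-tailed (upper-tail) p-value, the standard convention for
goodness-of-fit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as chi2_dist

from .core import DataError


@dataclass(frozen=True)
class SegregationResult:
    n_class_a: int
    n_class_b: int
    ratio_a: float
    ratio_b: float
    chi2: float
    p_value: float

    @property
    def expected(self) -> tuple[float, float]:
        total = self.n_class_a + self.n_class_b
        s = self.ratio_a + self.ratio_b
        return total * self.ratio_a / s, total * self.ratio_b / s

    @property
    def significant_5pct(self) -> bool:
        """Exceeds the 3.84 critical value of the 1-df chi-square."""
        return self.p_value < 0.05


def chisq_segregation(
    n_a: int, n_b: int, ratio_a: float = 3, ratio_b: float = 1
) -> SegregationResult:
    """Test observed counts ``n_a:n_b`` against an expected ratio.

    >>> chisq_segregation(49, 19).chi2
    0.3137254901960784
    """
    if n_a < 0 or n_b < 0:
        raise DataError("observed counts must be non-negative")
    total = n_a + n_b
    if total <= 0:
        raise DataError("cannot test an empty sample")
    if ratio_a <= 0 or ratio_b <= 0:
        raise DataError("ratio terms must be positive")
    s = ratio_a + ratio_b
    exp_a = total * ratio_a / s
    exp_b = total * ratio_b / s
    chi2 = (n_a - exp_a) ** 2 / exp_a + (n_b - exp_b) ** 2 / exp_b
    p = float(chi2_dist.sf(chi2, df=1))
    return SegregationResult(n_a, n_b, ratio_a, ratio_b, float(chi2), p)
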