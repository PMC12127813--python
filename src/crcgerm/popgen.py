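"""Population-genetic statistics: allele frequencies, Hardy-Weinberg
goodness of fit, and case-vs-reference allele-frequency comparisons.

The Hardy-Weinberg test is the classical chi-square goodness-of-fit form
with one degree of freedom: expected genotype counts p^2, 2pq, q^2 are
computed from the allele frequency estimated on the same sample, leaving
3 - 1 (estimated parameter) - 1 = 1 df. Case-vs-reference comparisons are
Pearson chi-square tests on the 2x2 allele-count table, optionally with
the Yates continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "GenotypeCounts",
    "FreqComparison",
    "allele_freqs",
    "hwe_chi2",
    "freq_compare",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic site."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one genotype is required")

    @property
    def total(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom


@dataclass(frozen=True)
class FreqComparison:
    case_alt: int
    case_total: int
    ref_alt: int
    ref_total: int
    chi2: float
    p: float
    yates: bool


def allele_freqs(g: GenotypeCounts) -> tuple[float, float]:
    """Sample allele frequencies (p_ref, p_alt) from genotype counts."""
    n_alleles = 2 * g.total
    p_alt = (g.n_het + 2 * g.n_alt_hom) / n_alleles
    return 1.0 - p_alt, p_alt


def hwe_chi2(g: GenotypeCounts) -> tuple[float, float, bool]:
    """Chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    Returns ``(chi2, p, degenerate)``. Expected counts are n*(p^2, 2pq, q^2)
    with p estimated from the sample; the p-value is the upper tail of the
    1-df chi-square distribution. At a monomorphic site the estimated
    frequency forces the expectations onto the observations; zero-expectation
    cells contribute nothing and ``degenerate`` is set.
    """
    n = g.total
    p_ref, p_alt = allele_freqs(g)
    expected = (n * p_ref**2, n * 2 * p_ref * p_alt, n * p_alt**2)
    observed = (g.n_ref_hom, g.n_het, g.n_alt_hom)
    chi2 = 0.0
    degenerate = False
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            degenerate = True
            continue
        chi2 += (obs - exp) ** 2 / exp
    if degenerate:
        warnings.warn(
            "zero expected genotype count; corresponding term skipped",
            stacklevel=2,
        )
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, degenerate


def freq_compare(
    case_alt: int,
    case_total: int,
    ref_alt: int,
    ref_total: int,
    yates: bool = False,
) -> FreqComparison:
    """Pearson chi-square on the 2x2 allele-count table case vs reference.

    Totals are allele numbers (2N for diploid samples). Raises when any
    table margin is zero, where the test is undefined.
    """
    if not (0 <= case_alt <= case_total and 0 <= ref_alt <= ref_total):
        raise ValueError("alt counts must lie between 0 and the allele total")
    table = [
        [case_alt, case_total - case_alt],
        [ref_alt, ref_total - ref_alt],
    ]
    row_margins = [sum(r) for r in table]
    col_margins = [table[0][j] + table[1][j] for j in range(2)]
    if min(row_margins) == 0 or min(col_margins) == 0:
        raise ValueError("chi-square test undefined: zero table margin")
    res = stats.chi2_contingency(table, correction=yates)
    return FreqComparison(
        case_alt=case_alt,
        case_total=case_total,
        ref_alt=ref_alt,
        ref_total=ref_total,
        chi2=float(res.statistic),
        p=float(res.pvalue),
        yates=yates,
    )
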