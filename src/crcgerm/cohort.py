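"""Bivariate association analysis of clinical variables against age at
diagnosis (early-onset vs late-onset, default cut at 50 years).

Each categorical clinical variable is tested with a Pearson chi-square on
a 2x2 table (variable level vs age group), reported both uncorrected and
with the Yates continuity correction. Binary variables give one table;
multi-level variables (tumour site, histology) are expanded one-vs-rest,
one table per level. ``unknown`` rows are excluded before testing by
default, so the effective n varies per variable.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .models import PatientRecord

__all__ = ["ContingencyTable", "chi2_2x2", "build_tables", "association_report", "chi2_rx2"]

#: PatientRecord attributes eligible for association testing.
TESTABLE_VARIABLES = (
    "sex",
    "family_history_cancer",
    "family_history_crc",
    "tumor_site",
    "stage",
    "metastasis",
    "lymphovascular",
)

_BINARY_VOCABS: dict[str, tuple[str, str]] = {
    "sex": ("male", "female"),
    "family_history_cancer": ("yes", "no"),
    "family_history_crc": ("yes", "no"),
    "metastasis": ("yes", "no"),
    "lymphovascular": ("yes", "no"),
}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = level present / absent, columns = age <cut / >=cut."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


def chi2_2x2(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, optional Yates correction.

    Equivalent to chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with Yates,
    |ad-bc| is shrunk by n/2 and floored at zero. Raises on a zero margin.
    """
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        raise ValueError("chi-square test undefined: zero table margin")
    res = stats.chi2_contingency(t.cells, correction=yates)
    return float(res.statistic), float(res.pvalue)


def chi2_rx2(levels_by_age: Sequence[tuple[int, int]]) -> tuple[float, float, int]:
    """Pearson chi-square on an Rx2 table of level counts by age group.

    Used for pooled multi-level blocks; returns (chi2, p, df). Levels with
    zero totals are dropped first.
    """
    rows = [r for r in levels_by_age if sum(r) > 0]
    if len(rows) < 2:
        raise ValueError("Rx2 test needs at least two non-empty levels")
    res = stats.chi2_contingency(rows, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def build_tables(
    patients: Iterable[PatientRecord],
    variable: str,
    age_cut: float = 50.0,
    unknown_policy: str = "exclude",
) -> list[tuple[str, ContingencyTable]]:
    """Contingency tables for one clinical variable against the age split.

    Binary variables yield a single (level, table) pair for their reference
    level; multi-level variables yield one one-vs-rest pair per observed
    level. Under ``unknown_policy='exclude'`` patients with the value
    ``unknown`` are dropped before tabulation.
    """
    if variable not in TESTABLE_VARIABLES:
        raise ValueError(f"unknown clinical variable: {variable!r}")
    if unknown_policy not in ("exclude", "keep"):
        raise ValueError(f"unknown unknown_policy: {unknown_policy!r}")

    rows = [(getattr(p, variable), p.age_at_dx < age_cut) for p in patients]
    if unknown_policy == "exclude":
        rows = [(v, young) for v, young in rows if v != "unknown"]
    if not rows:
        raise ValueError(f"no usable patients for variable {variable!r}")

    def table_for(level: str) -> ContingencyTable:
        a = sum(1 for v, young in rows if v == level and young)
        b = sum(1 for v, young in rows if v == level and not young)
        c = sum(1 for v, young in rows if v != level and young)
        d = sum(1 for v, young in rows if v != level and not young)
        return ContingencyTable(a, b, c, d)

    if variable in _BINARY_VOCABS:
        level = _BINARY_VOCABS[variable][0]
        return [(level, table_for(level))]
    levels = sorted({v for v, _ in rows})
    return [(level, table_for(level)) for level in levels]


def association_report(
    patients: Sequence[PatientRecord],
    variables: Sequence[str] = TESTABLE_VARIABLES,
    age_cut: float = 50.0,
    unknown_policy: str = "exclude",
) -> pd.DataFrame:
    """Chi-square association table over clinical variables, with and
    without the Yates correction, one row per tested level."""
    records = []
    for var in variables:
        for level, table in build_tables(patients, var, age_cut, unknown_policy):
            chi2, p = chi2_2x2(table)
            chi2_y, p_y = chi2_2x2(table, yates=True)
            records.append(
                {
                    "variable": var,
                    "level": level,
                    "n": table.n,
                    "young_with": table.a,
                    "old_with": table.b,
                    "chi2": chi2,
                    "p": p,
                    "chi2_yates": chi2_y,
                    "p_yates": p_y,
                }
            )
    return pd.DataFrame.from_records(records)
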