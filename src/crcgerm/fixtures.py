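"""Packaged reference fixtures: the published P/LP call set, the cohort's
clinicopathological count tables, and the three functionally validated
splice events.

These are small transcriptions of published summary tables, used as
regression anchors and as building blocks for synthetic cohorts. The
clinical counts are given per age-at-diagnosis group (under 50 vs 50 and
over; 12 and 88 patients respectively); ``cohort_patients`` expands them
into 100 patient records whose per-variable joint distribution with the
age split matches every published row (variables are assigned
independently of one another, which is all the bivariate analysis uses).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .models import PatientRecord
from .splicing import SpliceEvent, TranscriptModel

__all__ = [
    "plp_table",
    "table2_counts",
    "cohort_patients",
    "splice_cases",
]

N_PATIENTS = 100
N_YOUNG = 12  # diagnosed before 50


def plp_table() -> pd.DataFrame:
    """The 13 published P/LP calls: gene, HGVS, evidence criteria, verdict."""
    with resources.as_file(resources.files("crcgerm.data") / "plp_calls.tsv") as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return df


#: Clinical variable -> level -> (n age<50, n age>=50).
TABLE2_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {"male": (2, 43), "female": (10, 45)},
    "family_history_cancer": {"no": (3, 29), "yes": (8, 55), "unknown": (1, 4)},
    "family_history_crc": {"no": (6, 75), "yes": (4, 7), "unknown": (2, 6)},
    "tumor_site": {
        "right_colon": (2, 42),
        "sigmoid": (6, 23),
        "rectum": (4, 13),
        "entire_colon": (0, 1),
        "multiple_primary": (0, 9),
    },
    "stage": {
        "0": (1, 1),
        "I": (1, 13),
        "II": (4, 32),
        "III": (3, 29),
        "IV": (2, 13),
        "unknown": (1, 0),
    },
    "lymphovascular": {"yes": (8, 45), "no": (3, 42), "unknown": (1, 1)},
    "metastasis": {"yes": (2, 20), "no": (9, 67), "unknown": (1, 1)},
}


def table2_counts() -> dict[str, dict[str, tuple[int, int]]]:
    """Published per-variable counts by age group (copy)."""
    return {var: dict(levels) for var, levels in TABLE2_COUNTS.items()}


def cohort_patients() -> list[PatientRecord]:
    """100 patient records reproducing every published (variable x age
    group) count. Ages are placeholders within the correct side of the
    50-year cut (41 / 69 years)."""

    def expand(var: str, young: bool) -> list[str]:
        values: list[str] = []
        for level, (n_young, n_old) in TABLE2_COUNTS[var].items():
            values.extend([level] * (n_young if young else n_old))
        return values

    patients: list[PatientRecord] = []
    idx = 0
    for young, count, age in ((True, N_YOUNG, 41.0), (False, N_PATIENTS - N_YOUNG, 69.0)):
        columns = {var: expand(var, young) for var in TABLE2_COUNTS}
        for k in range(count):
            idx += 1
            patients.append(
                PatientRecord(
                    patient_id=f"P{idx:03d}",
                    sex=columns["sex"][k],
                    age_at_dx=age,
                    family_history_cancer=columns["family_history_cancer"][k],
                    family_history_crc=columns["family_history_crc"][k],
                    tumor_site=columns["tumor_site"][k],
                    stage=columns["stage"][k],
                    metastasis=columns["metastasis"][k],
                    lymphovascular=columns["lymphovascular"][k],
                )
            )
    return patients


def splice_cases() -> list[dict]:
    """The three minigene-validated splice events with their expected
    transcript consequences.

    Exon lengths other than the affected exon are schematic; the affected
    lengths (111, 100, 76, 98 bp) are the validated ones.
    """
    return [
        {
            "gene": "SMAD9",
            "hgvs_c": "c.781+2T>A",
            "model": TranscriptModel((120, 150, 111, 200)),
            "event": SpliceEvent("exon_skip", 3),
            "expected_kind": "in_frame_deletion",
            "expected_aa_removed": 37,
        },
        {
            "gene": "ERCC1",
            "hgvs_c": "c.702+1G>A",
            "model": TranscriptModel((100, 90, 80, 120, 130, 100, 140)),
            "event": SpliceEvent("exon_skip", 6),
            "expected_kind": "frameshift",
        },
        {
            "gene": "IL12RB1",
            "hgvs_c": "c.1791+2T>G (intron retention)",
            "model": TranscriptModel(tuple([100] * 17)),
            "event": SpliceEvent("intron_retention", 14, retained_length=98),
            "expected_kind": "frameshift",
        },
        {
            "gene": "IL12RB1",
            "hgvs_c": "c.1791+2T>G (exon skip)",
            "model": TranscriptModel(tuple([100] * 14 + [76, 100, 100])),
            "event": SpliceEvent("exon_skip", 15),
            "expected_kind": "frameshift",
        },
    ]
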