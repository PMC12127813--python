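"""Core domain types shared by every pipeline stage.

All score-like fields live on the unit interval; population allele
frequencies are fractions, never percentages. Missing annotations are
represented as ``None`` (``float('nan')`` is normalised to ``None`` on
construction) so that downstream filters decide their own semantics for
absent evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

PANEL_CATEGORIES = frozenset({"diagnostic", "candidate"})
PENETRANCE_LEVELS = frozenset({"high", "moderate", "less_well_defined", "unknown"})

EFFECT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "inframe_indel",
        "synonymous",
        "other",
    }
)
LOF_EFFECTS = frozenset({"nonsense", "frameshift", "splice_site"})

PREDICTORS = (
    "SIFT",
    "Polyphen2",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "FATHMM_MKL",
)
PREDICTOR_CALLS = frozenset({"deleterious", "tolerated", "missing"})

AM_CLASSES = frozenset({"likely_benign", "ambiguous", "likely_pathogenic"})

ZYGOSITIES = frozenset({"het", "hom"})

YES_NO_UNKNOWN = frozenset({"yes", "no", "unknown"})
SEXES = frozenset({"male", "female"})


def _norm_optional(x: float | None) -> float | None:
    if x is None:
        return None
    x = float(x)
    if math.isnan(x):
        return None
    return x


def _check_unit(name: str, x: float | None) -> float | None:
    x = _norm_optional(x)
    if x is not None and not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return x


@dataclass(frozen=True)
class GenePanelEntry:
    """One gene of the extended panel, with its provenance and penetrance."""

    symbol: str
    category: str
    penetrance: str = "unknown"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty gene symbol")
        if self.category not in PANEL_CATEGORIES:
            raise ValueError(f"unknown panel category: {self.category!r}")
        if self.penetrance not in PENETRANCE_LEVELS:
            raise ValueError(f"unknown penetrance level: {self.penetrance!r}")


@dataclass
class AnnotatedVariant:
    """A single annotated germline variant as consumed by both filters.

    ``predictor_calls`` always carries exactly the six missense predictors;
    absent calls are the explicit token ``"missing"`` so the voting
    denominator stays fixed at six.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    effect_class: str = "other"
    zygosity: str = "het"
    maf_global: float | None = None
    maf_latam: float | None = None
    predictor_calls: dict[str, str] = field(default_factory=dict)
    ada_score: float | None = None
    rf_score: float | None = None
    driver_scores: dict[str, float] = field(default_factory=dict)
    am_class: str | None = None
    am_score: float | None = None
    criteria: str | None = None
    patient_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class: {self.effect_class!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity: {self.zygosity!r}")
        calls = dict(self.predictor_calls)
        for name in PREDICTORS:
            calls.setdefault(name, "missing")
        unknown = set(calls) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictor names: {sorted(unknown)}")
        for name, call in calls.items():
            if call not in PREDICTOR_CALLS:
                raise ValueError(f"bad call {call!r} for predictor {name}")
        self.predictor_calls = calls
        self.maf_global = _check_unit("maf_global", self.maf_global)
        self.maf_latam = _check_unit("maf_latam", self.maf_latam)
        self.ada_score = _check_unit("ada_score", self.ada_score)
        self.rf_score = _check_unit("rf_score", self.rf_score)
        self.am_score = _check_unit("am_score", self.am_score)
        self.driver_scores = {
            tt: _check_unit(f"driver_scores[{tt}]", s)
            for tt, s in self.driver_scores.items()
        }
        if self.am_class is not None and self.am_class not in AM_CLASSES:
            raise ValueError(f"unknown AlphaMissense class: {self.am_class!r}")
        self.patient_ids = frozenset(self.patient_ids)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Genomic join key (chrom, pos, REF, ALT), alleles upper-cased."""
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())

    @property
    def is_lof(self) -> bool:
        return self.effect_class in LOF_EFFECTS


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical table."""

    patient_id: str
    sex: str
    age_at_dx: float
    family_history_cancer: str = "unknown"
    family_history_crc: str = "unknown"
    tumor_site: str = "unknown"
    stage: str = "unknown"
    metastasis: str = "unknown"
    lymphovascular: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex: {self.sex!r}")
        if not self.age_at_dx > 0:
            raise ValueError(f"age_at_dx must be positive, got {self.age_at_dx}")
        for name in ("family_history_cancer", "family_history_crc", "metastasis", "lymphovascular"):
            if getattr(self, name) not in YES_NO_UNKNOWN:
                raise ValueError(f"{name} must be yes/no/unknown, got {getattr(self, name)!r}")
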