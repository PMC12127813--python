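"""Filter B: driver-score flagging of rare variants.

Variants below 5% global MAF (strict, per the filter's definition; missing
MAF passes) that carry at least one per-tumour-type driver score are
evaluated against a decision threshold (default 0.5, the natural boundary
of a calibrated probability-like score). The colorectal tumour-type score
("COREAD") is preferred when present; otherwise the variant's best
available tumour type is used.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .models import AnnotatedVariant, GenePanelEntry

__all__ = [
    "OncodriverCall",
    "filter_b",
    "call_oncodriver",
    "call_cohort",
    "summarize_oncodrivers",
]

DEFAULT_TUMOR_TYPE = "COREAD"


@dataclass(frozen=True)
class OncodriverCall:
    variant: AnnotatedVariant
    tumor_type: str
    score: float
    is_driver: bool


def filter_b(
    variants: Iterable[AnnotatedVariant],
    maf_threshold: float = 0.05,
) -> list[AnnotatedVariant]:
    """Frequency gate for the driver-score track: strict MAF < threshold
    (missing MAF passes) and at least one driver score present."""
    if not 0.0 < maf_threshold <= 1.0:
        raise ValueError("maf_threshold must lie in (0, 1]")
    out = []
    for v in variants:
        if v.maf_global is not None and v.maf_global >= maf_threshold:
            continue
        if not v.driver_scores:
            continue
        out.append(v)
    return out


def call_oncodriver(
    v: AnnotatedVariant,
    tumor_type: str = DEFAULT_TUMOR_TYPE,
    threshold: float = 0.5,
) -> OncodriverCall:
    """Flag one variant from its driver score in the given tumour type
    (inclusive threshold). Raises if the variant has no score there."""
    if tumor_type not in v.driver_scores:
        raise KeyError(f"variant {v.gene} has no driver score for tumour type {tumor_type!r}")
    score = v.driver_scores[tumor_type]
    return OncodriverCall(v, tumor_type, score, score >= threshold)


def _pick_tumor_type(v: AnnotatedVariant, preferred: str) -> str:
    if preferred in v.driver_scores:
        return preferred
    # deterministic fallback: best score, ties broken alphabetically
    return max(sorted(v.driver_scores), key=lambda tt: v.driver_scores[tt])


def call_cohort(
    variants: Iterable[AnnotatedVariant],
    maf_threshold: float = 0.05,
    threshold: float = 0.5,
    tumor_type: str = DEFAULT_TUMOR_TYPE,
) -> list[OncodriverCall]:
    """Filter B end to end: frequency gate, then one call per variant using
    the preferred tumour type where scored."""
    calls = []
    for v in filter_b(variants, maf_threshold):
        tt = _pick_tumor_type(v, tumor_type)
        calls.append(call_oncodriver(v, tt, threshold))
    return calls


def summarize_oncodrivers(
    calls: Sequence[OncodriverCall],
    panel: Sequence[GenePanelEntry] = (),
    n_patients: int | None = None,
) -> dict:
    """Cohort summary of positive driver calls.

    Reports variant and gene counts, the fraction of patients carrying at
    least one / more than one driver variant (when carrier identifiers and
    a cohort size are available), and the distribution of calls over panel
    category, penetrance and effect class. Percentages are fractions of
    the positive-call set, rounded to one decimal when formatted.
    """
    drivers = [c for c in calls if c.is_driver]
    by_category = {e.symbol: e.category for e in panel}
    by_penetrance = {e.symbol: e.penetrance for e in panel}

    genes = sorted({c.variant.gene for c in drivers})
    carrier_counts: dict[str, int] = {}
    for c in drivers:
        for pid in c.variant.patient_ids:
            carrier_counts[pid] = carrier_counts.get(pid, 0) + 1

    def share_table(keyfn) -> dict[str, float]:
        counts: dict[str, int] = {}
        for c in drivers:
            k = keyfn(c)
            counts[k] = counts.get(k, 0) + 1
        total = len(drivers)
        return {k: counts[k] / total for k in sorted(counts)} if total else {}

    summary: dict = {
        "n_driver_variants": len(drivers),
        "n_genes": len(genes),
        "genes": genes,
        "effect_class_share": share_table(lambda c: c.variant.effect_class),
        "panel_category_share": share_table(
            lambda c: by_category.get(c.variant.gene, "unknown")
        ),
        "penetrance_share": share_table(
            lambda c: by_penetrance.get(c.variant.gene, "unknown")
        ),
    }
    summary["n_carriers"] = len(carrier_counts)
    summary["n_multi_carriers"] = sum(1 for k in carrier_counts.values() if k > 1)
    if n_patients:
        summary["detection_rate"] = len(carrier_counts) / n_patients
        summary["multi_carrier_rate"] = summary["n_multi_carriers"] / n_patients
    return summary
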