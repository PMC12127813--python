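"""End-to-end cohort analysis: triage, classification, driver flagging and
cohort statistics, collected into one report.

The report mirrors the headline summaries a germline screening study
reports: variant counts and shares per five-class verdict, the per-patient
detection rate of pathogenic / likely-pathogenic (P/LP) variants (a
patient with several qualifying variants counts once), oncodriver carrier
rates, per-gene and per-panel-category tallies, Hardy-Weinberg tests per
variant, and the clinical association table. Percentages are rounded to
one decimal in the human-readable report; machine output keeps full
precision.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .acmg import classify, parse_criteria
from .cohort import association_report
from .models import AnnotatedVariant, GenePanelEntry, PatientRecord
from .oncodriver import call_cohort, summarize_oncodrivers
from .popgen import GenotypeCounts, allele_freqs, hwe_chi2
from .triage import TriageConfig, filter_a, gate_counts

__all__ = ["PipelineConfig", "run_pipeline", "detection_rate", "class_shares", "write_report"]

VERDICT_ORDER = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "likely_benign",
    "benign",
)


@dataclass(frozen=True)
class PipelineConfig:
    triage: TriageConfig = field(default_factory=TriageConfig)
    conflict_policy: str = "override_bp"
    driver_maf_threshold: float = 0.05
    driver_threshold: float = 0.5
    tumor_type: str = "COREAD"
    age_cut: float = 50.0

    def as_dict(self) -> dict:
        return {
            "maf_threshold": self.triage.maf_threshold,
            "maf_missing_passes": self.triage.maf_missing_passes,
            "splice_cutoff": self.triage.splice_cutoff,
            "splice_require_both": self.triage.splice_require_both,
            "min_votes": self.triage.min_votes,
            "conflict_policy": self.conflict_policy,
            "driver_maf_threshold": self.driver_maf_threshold,
            "driver_threshold": self.driver_threshold,
            "tumor_type": self.tumor_type,
            "age_cut": self.age_cut,
        }


def detection_rate(n_carriers: int, n_patients: int) -> float:
    """Fraction of patients carrying at least one qualifying variant."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0 <= n_carriers <= n_patients:
        raise ValueError("carrier count outside 0..n_patients")
    return n_carriers / n_patients


def class_shares(counts: dict[str, int]) -> dict[str, float]:
    """Per-class shares of a count table, as fractions of the total."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: v / total for k, v in counts.items()}


def _genotype_counts(v: AnnotatedVariant, n_patients: int) -> GenotypeCounts:
    n_hom = len(v.patient_ids) if v.zygosity == "hom" else 0
    n_het = len(v.patient_ids) if v.zygosity == "het" else 0
    return GenotypeCounts(
        n_ref_hom=n_patients - n_hom - n_het, n_het=n_het, n_alt_hom=n_hom
    )


def run_pipeline(
    variants: Sequence[AnnotatedVariant],
    patients: Sequence[PatientRecord],
    panel: Sequence[GenePanelEntry] = (),
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run both filtering tracks and the cohort statistics; return the
    report as a JSON-serialisable dict."""
    n_patients = len(patients)
    report: dict = {
        "crcgerm_version": __version__,
        "config": config.as_dict(),
        "n_patients": n_patients,
        "n_variants_input": len(variants),
    }

    # --- track A: triage + ACMG/AMP classification -----------------------
    decisions = filter_a(variants, config.triage)
    report["triage"] = gate_counts(decisions)

    verdict_counts = dict.fromkeys(VERDICT_ORDER, 0)
    plp_variants: list[AnnotatedVariant] = []
    per_gene_plp: dict[str, int] = {}
    for d in decisions:
        if not d.retained:
            continue
        ev = parse_criteria(d.variant.criteria or "")
        result = classify(ev, config.conflict_policy)
        verdict_counts[result.verdict] += 1
        if result.verdict in ("pathogenic", "likely_pathogenic"):
            plp_variants.append(d.variant)
            per_gene_plp[d.variant.gene] = per_gene_plp.get(d.variant.gene, 0) + 1

    report["acmg"] = {
        "verdict_counts": verdict_counts,
        "verdict_shares": class_shares(verdict_counts),
        "n_plp_variants": len(plp_variants),
        "per_gene_plp": dict(sorted(per_gene_plp.items())),
    }
    plp_carriers = sorted({pid for v in plp_variants for pid in v.patient_ids})
    report["acmg"]["n_plp_carriers"] = len(plp_carriers)
    if n_patients:
        report["acmg"]["plp_detection_rate"] = detection_rate(len(plp_carriers), n_patients)

    by_cat = {e.symbol: e.category for e in panel}
    by_pen = {e.symbol: e.penetrance for e in panel}
    cat_counts: dict[str, int] = {}
    pen_counts: dict[str, int] = {}
    for v in plp_variants:
        cat = by_cat.get(v.gene, "unknown")
        pen = by_pen.get(v.gene, "unknown")
        cat_counts[cat] = cat_counts.get(cat, 0) + 1
        pen_counts[pen] = pen_counts.get(pen, 0) + 1
    report["acmg"]["panel_category_shares"] = class_shares(dict(sorted(cat_counts.items())))
    report["acmg"]["penetrance_shares"] = class_shares(dict(sorted(pen_counts.items())))

    # --- track B: oncodriver flagging ------------------------------------
    calls = call_cohort(
        variants,
        maf_threshold=config.driver_maf_threshold,
        threshold=config.driver_threshold,
        tumor_type=config.tumor_type,
    )
    report["oncodriver"] = summarize_oncodrivers(calls, panel, n_patients or None)

    # --- population-genetic table ----------------------------------------
    hwe_rows = []
    if n_patients:
        for i, v in enumerate(variants):
            if not v.patient_ids:
                continue
            g = _genotype_counts(v, n_patients)
            chi2, p, degenerate = hwe_chi2(g)
            _, p_alt = allele_freqs(g)
            hwe_rows.append(
                {
                    "variant_index": i,
                    "gene": v.gene,
                    "p_alt": p_alt,
                    "hwe_chi2": chi2,
                    "hwe_p": p,
                    "degenerate": degenerate,
                }
            )
    report["popgen"] = {"n_tested": len(hwe_rows), "hwe": hwe_rows}

    # --- clinical association table --------------------------------------
    if patients:
        assoc = association_report(patients, age_cut=config.age_cut)
        report["cohort_associations"] = assoc.to_dict("records")
    else:
        report["cohort_associations"] = []

    return report


def _fmt_pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def render_text_report(report: dict) -> str:
    """Plain-text rendering with one-decimal percentages."""
    lines = [
        f"crcgerm cohort report (v{report['crcgerm_version']})",
        "=" * 46,
        f"patients: {report['n_patients']}   variants: {report['n_variants_input']}",
        "",
        "thresholds: "
        + ", ".join(f"{k}={v}" for k, v in sorted(report["config"].items())),
        "",
        "Filter A / ACMG-AMP classification",
        "-" * 34,
    ]
    acmg = report["acmg"]
    for verdict in VERDICT_ORDER:
        n = acmg["verdict_counts"][verdict]
        lines.append(
            f"  {verdict:<24} {n:>4}  ({_fmt_pct(acmg['verdict_shares'][verdict])})"
        )
    if "plp_detection_rate" in acmg:
        lines.append(
            f"  P/LP carriers: {acmg['n_plp_carriers']} "
            f"({_fmt_pct(acmg['plp_detection_rate'])} of patients)"
        )
    onc = report["oncodriver"]
    lines += [
        "",
        "Filter B / oncodriver calls",
        "-" * 27,
        f"  driver variants: {onc['n_driver_variants']} in {onc['n_genes']} genes",
    ]
    if "detection_rate" in onc:
        lines.append(
            f"  carriers: {onc['n_carriers']} ({_fmt_pct(onc['detection_rate'])}); "
            f">1 variant: {onc['n_multi_carriers']} ({_fmt_pct(onc['multi_carrier_rate'])})"
        )
    for name, table in (
        ("effect class", onc["effect_class_share"]),
        ("panel category", onc["panel_category_share"]),
        ("penetrance", onc["penetrance_share"]),
    ):
        if table:
            lines.append(
                f"  by {name}: "
                + ", ".join(f"{k} {_fmt_pct(v)}" for k, v in table.items())
            )
    lines.append("")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the JSON summary and the plain-text report deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.txt", "w") as fh:
        fh.write(render_text_report(report))
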