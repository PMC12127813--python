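"""Readers and writers for the flat tables the pipeline consumes.

TSV is the canonical dialect: one variant per row, missing annotations as
empty cells (never zero-filled), per-tumour-type driver scores packed as
``TYPE:score`` pairs separated by ``;``. VCF input is supported by mapping
a documented set of INFO keys onto the same schema (see ``VCF_INFO_KEYS``).
All readers raise with a row/record reference on malformed input.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from importlib import resources
from pathlib import Path

from .models import (
    PREDICTORS,
    AnnotatedVariant,
    GenePanelEntry,
    PatientRecord,
)

__all__ = [
    "load_panel",
    "packaged_panel",
    "read_variant_table",
    "write_results_table",
    "read_clinical_table",
    "write_clinical_table",
    "VARIANT_COLUMNS",
]


class TableFormatError(ValueError):
    """Malformed row or field in an input table."""


# ---------------------------------------------------------------- panel ----

PANEL_COLUMNS = ("symbol", "category", "penetrance")


def load_panel(path: str | Path) -> list[GenePanelEntry]:
    """Load a gene panel TSV with columns symbol, category, penetrance.

    Duplicate symbols and unknown category/penetrance tokens are rejected
    with the offending row number.
    """
    entries: list[GenePanelEntry] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PANEL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise TableFormatError(f"panel file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                entry = GenePanelEntry(
                    symbol=row["symbol"].strip(),
                    category=row["category"].strip(),
                    penetrance=row["penetrance"].strip() or "unknown",
                )
            except ValueError as exc:
                raise TableFormatError(f"{path}: row {i}: {exc}") from exc
            if entry.symbol in seen:
                raise TableFormatError(f"{path}: row {i}: duplicate symbol {entry.symbol!r}")
            seen.add(entry.symbol)
            entries.append(entry)
    return entries


def packaged_panel() -> list[GenePanelEntry]:
    """The packaged 206-gene colorectal panel (102 diagnostic, 104 candidate)."""
    with resources.as_file(resources.files("crcgerm.data") / "panel.tsv") as p:
        return load_panel(p)


# ------------------------------------------------------------- variants ----

VARIANT_COLUMNS: tuple[str, ...] = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "effect_class",
    "zygosity",
    "maf_global",
    "maf_latam",
    *(f"pred_{p}" for p in PREDICTORS),
    "ada_score",
    "rf_score",
    "driver_scores",
    "am_class",
    "am_score",
    "criteria",
    "patient_ids",
)

#: VCF INFO keys carrying each annotation (dialect=vcf).
VCF_INFO_KEYS = {
    "gene": "GENE",
    "transcript": "TRANSCRIPT",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "effect_class": "EFFECT",
    "zygosity": "ZYG",
    "maf_global": "MAF_G",
    "maf_latam": "MAF_L",
    "ada_score": "ADA",
    "rf_score": "RF",
    "am_class": "AM_CLASS",
    "am_score": "AM_SCORE",
    "criteria": "CRITERIA",
    "patient_ids": "CARRIERS",
}


def _opt_float(cell: str, where: str) -> float | None:
    if cell == "" or cell == ".":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise TableFormatError(f"{where}: not a number: {cell!r}") from exc


def _pack_driver_scores(scores: dict[str, float]) -> str:
    # repr gives the shortest digit string that round-trips exactly
    return ";".join(f"{tt}:{scores[tt]!r}" for tt in sorted(scores))


def _unpack_driver_scores(cell: str, where: str) -> dict[str, float]:
    if not cell:
        return {}
    out: dict[str, float] = {}
    for item in cell.split(";"):
        if ":" not in item:
            raise TableFormatError(f"{where}: bad driver-score item {item!r}")
        tt, s = item.split(":", 1)
        out[tt] = float(s)
    return out


def _row_to_variant(row: dict[str, str], where: str) -> AnnotatedVariant:
    try:
        calls = {
            p: (row.get(f"pred_{p}", "") or "missing") for p in PREDICTORS
        }
        return AnnotatedVariant(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            transcript=row.get("transcript", ""),
            hgvs_c=row.get("hgvs_c") or None,
            hgvs_p=row.get("hgvs_p") or None,
            effect_class=row.get("effect_class", "other"),
            zygosity=row.get("zygosity") or "het",
            maf_global=_opt_float(row.get("maf_global", ""), where),
            maf_latam=_opt_float(row.get("maf_latam", ""), where),
            predictor_calls=calls,
            ada_score=_opt_float(row.get("ada_score", ""), where),
            rf_score=_opt_float(row.get("rf_score", ""), where),
            driver_scores=_unpack_driver_scores(row.get("driver_scores", ""), where),
            am_class=row.get("am_class") or None,
            am_score=_opt_float(row.get("am_score", ""), where),
            criteria=row.get("criteria") or None,
            patient_ids=frozenset(
                p for p in row.get("patient_ids", "").split(";") if p
            ),
        )
    except (KeyError, ValueError) as exc:
        raise TableFormatError(f"{where}: {exc}") from exc


def _variant_to_row(v: AnnotatedVariant) -> dict[str, str]:
    def fmt(x) -> str:
        return "" if x is None else (repr(x) if isinstance(x, float) else str(x))

    row = {
        "chrom": v.chrom,
        "pos": str(v.pos),
        "ref": v.ref,
        "alt": v.alt,
        "gene": v.gene,
        "transcript": v.transcript,
        "hgvs_c": v.hgvs_c or "",
        "hgvs_p": v.hgvs_p or "",
        "effect_class": v.effect_class,
        "zygosity": v.zygosity,
        "maf_global": fmt(v.maf_global),
        "maf_latam": fmt(v.maf_latam),
        "ada_score": fmt(v.ada_score),
        "rf_score": fmt(v.rf_score),
        "driver_scores": _pack_driver_scores(v.driver_scores),
        "am_class": v.am_class or "",
        "am_score": fmt(v.am_score),
        "criteria": v.criteria or "",
        "patient_ids": ";".join(sorted(v.patient_ids)),
    }
    for p in PREDICTORS:
        call = v.predictor_calls.get(p, "missing")
        row[f"pred_{p}"] = "" if call == "missing" else call
    return row


def _read_vcf(path: str | Path) -> list[AnnotatedVariant]:
    from cyvcf2 import VCF

    variants: list[AnnotatedVariant] = []
    for i, rec in enumerate(VCF(str(path)), start=1):
        where = f"{path}: record {i}"
        if len(rec.ALT) != 1:
            raise TableFormatError(f"{where}: expected exactly one ALT allele")

        def info(key: str):
            val = rec.INFO.get(key)
            return None if val is None else str(val)

        row: dict[str, str] = {
            "chrom": rec.CHROM,
            "pos": str(rec.POS),
            "ref": rec.REF,
            "alt": rec.ALT[0],
            "gene": info("GENE") or "",
        }
        for field, key in VCF_INFO_KEYS.items():
            if field == "gene":
                continue
            val = info(key)
            if val is not None:
                row[field] = val
        for p in PREDICTORS:
            val = info(f"PRED_{p}")
            if val is not None:
                row[f"pred_{p}"] = val
        driver = {}
        for key, val in dict(rec.INFO).items():
            if key.startswith("BDM_"):
                driver[key[4:]] = float(val)
        row["driver_scores"] = _pack_driver_scores(driver)
        variants.append(_row_to_variant(row, where))
    return variants


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[AnnotatedVariant]:
    """Read an annotated variant table in the TSV or VCF dialect.

    Missing annotations stay missing; out-of-range scores and malformed
    rows raise :class:`TableFormatError` naming the offending row.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    variants: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            variants.append(_row_to_variant(row, f"{path}: row {i}"))
    return variants


def write_results_table(
    variants: Iterable[AnnotatedVariant],
    path: str | Path,
    extra_columns: Sequence[dict[str, str]] | None = None,
) -> None:
    """Write variants as TSV in the canonical column order, re-readable by
    :func:`read_variant_table`. ``extra_columns`` optionally appends
    parallel per-variant columns (e.g. triage route, verdict)."""
    variants = list(variants)
    extras = list(extra_columns or [])
    if extras and len(extras) != len(variants):
        raise ValueError("extra_columns must parallel the variant list")
    extra_names = sorted({k for d in extras for k in d})
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=[*VARIANT_COLUMNS, *extra_names], delimiter="\t"
        )
        writer.writeheader()
        for i, v in enumerate(variants):
            row = _variant_to_row(v)
            if extras:
                row.update(extras[i])
            writer.writerow(row)


# ------------------------------------------------------------- clinical ----

CLINICAL_COLUMNS = (
    "patient_id",
    "sex",
    "age_at_dx",
    "family_history_cancer",
    "family_history_crc",
    "tumor_site",
    "stage",
    "metastasis",
    "lymphovascular",
)


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the patient clinical TSV."""
    out: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    PatientRecord(
                        patient_id=row["patient_id"],
                        sex=row["sex"],
                        age_at_dx=float(row["age_at_dx"]),
                        family_history_cancer=row.get("family_history_cancer", "unknown"),
                        family_history_crc=row.get("family_history_crc", "unknown"),
                        tumor_site=row.get("tumor_site", "unknown"),
                        stage=row.get("stage", "unknown"),
                        metastasis=row.get("metastasis", "unknown"),
                        lymphovascular=row.get("lymphovascular", "unknown"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise TableFormatError(f"{path}: row {i}: {exc}") from exc
    return out


def write_clinical_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(CLINICAL_COLUMNS), delimiter="\t")
        writer.writeheader()
        for p in patients:
            writer.writerow({c: getattr(p, c) for c in CLINICAL_COLUMNS})
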