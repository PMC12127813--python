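"""Synthetic annotated cohorts for exercising the full pipeline.

The generator emulates the study conditions the pipeline was designed for:
100 unselected colorectal-cancer patients screened over a 206-gene panel,
with 12% of patients planted as carriers of a pathogenic/likely-pathogenic
variant and 65% as carriers of an oncodriver variant. Planting is exact —
carrier patients are chosen without replacement, so the planted detection
rates are sharp — while annotation noise enters through decoy variants and
through the class-conditional driver-score draws.

Planted P/LP variants carry evidence-code combinations sampled from the 13
published call-set rows, so the pathogenic : likely-pathogenic class ratio
(5:8) is reproduced in expectation. Decoy variants are constructed to fail
specific gates (common alleles, failed predictor votes, synonymous
changes) or to classify as VUS / likely benign, populating the non-P/LP
classes of the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import plp_table
from .models import PREDICTORS, AnnotatedVariant, PatientRecord
from .concordance import ScoredVariantPair
from .popgen import GenotypeCounts

__all__ = [
    "SyntheticCohortSpec",
    "gen_cohort",
    "gen_hwe_genotypes",
    "gen_hwe_replicates",
    "gen_score_pairs",
]

_EFFECT_BY_TYPE = {"missense": "missense", "lof": "frameshift", "splice": "splice_site"}

#: Effect-class mix of planted driver variants (missense-dominated, as in
#: driver-score call sets).
_DRIVER_EFFECT_MIX = (
    ("missense", 0.824),
    ("frameshift", 0.132),
    ("splice_site", 0.015),
    ("synonymous", 0.029),
)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 100
    n_variants: int = 248
    planted_plp_rate: float = 0.12
    planted_driver_rate: float = 0.65
    maf_beta: tuple[float, float] = (0.5, 200.0)  # rare-variant MAF distribution
    predictor_agreement: float = 0.9
    score_beta_pos: tuple[float, float] = (8.0, 2.0)
    score_beta_neg: tuple[float, float] = (2.0, 8.0)
    tumor_type: str = "COREAD"
    seed: int = 0
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("planted_plp_rate", "planted_driver_rate", "predictor_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 1 or self.n_variants < 1:
            raise ValueError("n_patients and n_variants must be >= 1")


def _random_alleles(rng: np.random.Generator) -> tuple[str, str]:
    bases = ["A", "C", "G", "T"]
    ref = bases[rng.integers(4)]
    alt = bases[rng.integers(4)]
    while alt == ref:
        alt = bases[rng.integers(4)]
    return ref, alt


def _predictor_calls(rng: np.random.Generator, deleterious: bool, agreement: float, min_votes: int = 3) -> dict[str, str]:
    if deleterious:
        votes = rng.random(6) < agreement
        while votes.sum() < min_votes:  # planted variants must survive the vote
            votes = rng.random(6) < agreement
    else:
        votes = rng.random(6) < 0.15
        while votes.sum() >= min_votes:  # decoys must fail it
            votes = rng.random(6) < 0.15
    return {
        p: ("deleterious" if v else "tolerated") for p, v in zip(PREDICTORS, votes)
    }


def _gen_patients(spec: SyntheticCohortSpec, rng: np.random.Generator) -> list[PatientRecord]:
    sites = ("right_colon", "sigmoid", "rectum", "entire_colon", "multiple_primary")
    stages = ("0", "I", "II", "III", "IV")
    patients = []
    for i in range(spec.n_patients):
        age = float(np.clip(rng.normal(65.5, 12.6), 25.0, 95.0))
        patients.append(
            PatientRecord(
                patient_id=f"S{i + 1:04d}",
                sex="female" if rng.random() < 0.55 else "male",
                age_at_dx=round(age, 1),
                family_history_cancer="yes" if rng.random() < 0.63 else "no",
                family_history_crc="yes" if rng.random() < 0.11 else "no",
                tumor_site=sites[rng.choice(5, p=[0.44, 0.29, 0.17, 0.01, 0.09])],
                stage=stages[rng.choice(5, p=[0.02, 0.14, 0.37, 0.32, 0.15])],
                metastasis="yes" if rng.random() < 0.22 else "no",
                lymphovascular="yes" if rng.random() < 0.53 else "no",
            )
        )
    return patients


def gen_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[AnnotatedVariant], list[PatientRecord], pd.DataFrame]:
    """Generate (variant table, patient table, truth table).

    The truth table has one row per variant with its planted class
    (``plp``, ``driver`` or ``decoy``) and carrier list; determinism is
    guaranteed by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    patients = _gen_patients(spec, rng)
    pids = [p.patient_id for p in patients]

    genes = list(spec.genes)
    if not genes:
        from .tables import packaged_panel

        genes = [e.symbol for e in packaged_panel()]

    n_plp_carriers = round(spec.planted_plp_rate * spec.n_patients)
    n_driver_carriers = round(spec.planted_driver_rate * spec.n_patients)
    plp_carriers = list(rng.choice(pids, size=n_plp_carriers, replace=False))
    driver_carriers = list(rng.choice(pids, size=n_driver_carriers, replace=False))

    plp_rows = plp_table().to_dict("records")
    variants: list[AnnotatedVariant] = []
    truth: list[dict] = []
    pos_counter = 1000

    def next_locus() -> tuple[str, int]:
        nonlocal pos_counter
        pos_counter += int(rng.integers(50, 5000))
        return f"chr{1 + int(rng.integers(22))}", pos_counter

    # --- planted P/LP variants: one per carrier, Table-3-style evidence ---
    for pid in plp_carriers:
        row = plp_rows[int(rng.integers(len(plp_rows)))]
        effect = _EFFECT_BY_TYPE[row["variant_type"]]
        chrom, pos = next_locus()
        ref, alt = _random_alleles(rng)
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=row["gene"],
            transcript=row["transcript"],
            hgvs_c=row["hgvs_c"],
            effect_class=effect,
            zygosity="het",
            maf_global=None if rng.random() < 0.3 else float(rng.uniform(1e-6, 1e-3)),
            predictor_calls=_predictor_calls(rng, True, spec.predictor_agreement)
            if effect == "missense"
            else {},
            ada_score=float(rng.uniform(0.8, 1.0)) if effect == "splice_site" else None,
            rf_score=float(rng.uniform(0.8, 1.0)) if effect == "splice_site" else None,
            criteria=row["criteria"],
            patient_ids={pid},
        )
        variants.append(v)
        truth.append(
            {
                "true_class": "plp",
                "expected_verdict": row["classification"],
                "carriers": pid,
            }
        )

    # --- planted driver variants: one per carrier, high score class ------
    effect_names = [e for e, _ in _DRIVER_EFFECT_MIX]
    effect_probs = np.array([p for _, p in _DRIVER_EFFECT_MIX])
    effect_probs = effect_probs / effect_probs.sum()
    a_pos, b_pos = spec.score_beta_pos
    for pid in driver_carriers:
        chrom, pos = next_locus()
        ref, alt = _random_alleles(rng)
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=genes[int(rng.integers(len(genes)))],
            effect_class=effect_names[int(rng.choice(len(effect_names), p=effect_probs))],
            maf_global=None if rng.random() < 0.2 else float(rng.beta(*spec.maf_beta) * 0.04),
            driver_scores={spec.tumor_type: float(rng.beta(a_pos, b_pos))},
            patient_ids={pid},
        )
        variants.append(v)
        truth.append({"true_class": "driver", "expected_verdict": "", "carriers": pid})

    # --- decoys ----------------------------------------------------------
    a_neg, b_neg = spec.score_beta_neg
    n_decoys = max(0, spec.n_variants - len(variants))
    decoy_kinds = ("common", "vote_fail", "synonymous", "vus", "lb")
    for _ in range(n_decoys):
        kind = decoy_kinds[int(rng.integers(len(decoy_kinds)))]
        chrom, pos = next_locus()
        ref, alt = _random_alleles(rng)
        gene = genes[int(rng.integers(len(genes)))]
        carriers = {pids[int(rng.integers(len(pids)))]}
        maf = float(rng.beta(*spec.maf_beta) * 0.009)
        effect, calls, criteria = "missense", _predictor_calls(rng, False, spec.predictor_agreement), None
        if kind == "common":
            maf = float(rng.uniform(0.05, 0.4))
        elif kind == "synonymous":
            effect, calls = "synonymous", {}
        elif kind == "vus":
            calls = _predictor_calls(rng, True, spec.predictor_agreement)
            criteria = "PM2"
        elif kind == "lb":
            calls = _predictor_calls(rng, True, spec.predictor_agreement)
            criteria = "BP1 + BP4"
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            effect_class=effect,
            maf_global=maf,
            predictor_calls=calls,
            driver_scores={spec.tumor_type: float(rng.beta(a_neg, b_neg))}
            if rng.random() < 0.5
            else {},
            criteria=criteria,
            patient_ids=carriers,
        )
        variants.append(v)
        truth.append({"true_class": "decoy", "expected_verdict": "", "carriers": sorted(carriers)[0]})

    truth_df = pd.DataFrame(truth)
    truth_df.insert(0, "variant_index", range(len(variants)))
    return variants, patients, truth_df


def gen_hwe_genotypes(p_alt: float, n: int, seed: int | np.random.Generator = 0) -> GenotypeCounts:
    """Genotype counts for ``n`` diploid individuals drawn exactly at HWE
    (two independent allele draws per individual)."""
    if not 0.0 <= p_alt <= 1.0:
        raise ValueError("p_alt must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alt_alleles = rng.binomial(2, p_alt, size=n)
    return GenotypeCounts(
        n_ref_hom=int(np.sum(alt_alleles == 0)),
        n_het=int(np.sum(alt_alleles == 1)),
        n_alt_hom=int(np.sum(alt_alleles == 2)),
    )


def gen_hwe_replicates(p_alt: float, n: int, reps: int, seed: int = 0) -> np.ndarray:
    """``reps`` independent HWE genotype draws, as a (reps, 3) count array.

    Vectorised equivalent of repeated :func:`gen_hwe_genotypes` calls, for
    calibration experiments.
    """
    rng = np.random.default_rng(seed)
    q = 1.0 - p_alt
    probs = np.array([q * q, 2 * q * p_alt, p_alt * p_alt])
    return rng.multinomial(n, probs, size=reps)


def gen_score_pairs(
    n_per_class: tuple[int, int],
    beta_pos: tuple[float, float] = (8.0, 2.0),
    beta_neg: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
    gene: str = "GENE1",
    tumor_type: str = "COREAD",
) -> list[ScoredVariantPair]:
    """Class-conditional Beta-distributed score pairs for one stratum:
    ``n_per_class = (n_pos, n_neg)`` positives labelled likely pathogenic
    and negatives likely benign."""
    rng = np.random.default_rng(seed)
    n_pos, n_neg = n_per_class
    pairs = [
        ScoredVariantPair(gene, tumor_type, float(s), "likely_pathogenic")
        for s in rng.beta(*beta_pos, size=n_pos)
    ]
    pairs += [
        ScoredVariantPair(gene, tumor_type, float(s), "likely_benign")
        for s in rng.beta(*beta_neg, size=n_neg)
    ]
    return pairs
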