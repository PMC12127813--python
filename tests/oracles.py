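"""Independent brute-force oracles used by the test suite.

Each oracle evaluates its rule set or formula literally and separately
from the package implementation, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2 as chi2_dist


def acmg_oracle(codes: frozenset[str], policy: str = "override_bp") -> str:
    """Literal clause-by-clause evaluation of the combining rules."""

    def n(prefix: str) -> int:
        if prefix == "PVS":
            return sum(1 for c in codes if c == "PVS1")
        if prefix == "BA":
            return sum(1 for c in codes if c == "BA1")
        return sum(1 for c in codes if c.startswith(prefix) and c not in ("PVS1", "BA1"))

    pvs, ps, pm, pp = n("PVS"), n("PS"), n("PM"), n("PP")
    ba, bs, bp = n("BA"), n("BS"), n("BP")
    p_side = pvs + ps + pm + pp > 0
    b_side = ba + bs + bp > 0

    if policy == "strict_vus" and p_side and b_side:
        return "uncertain_significance"

    pathogenic = (
        (pvs >= 1 and ps >= 1)
        or (pvs >= 1 and pm >= 2)
        or (pvs >= 1 and pm == 1 and pp == 1)
        or (pvs >= 1 and pm == 1 and pp > 1)
        or (pvs >= 1 and pp >= 2)
        or ps >= 2
        or (ps == 1 and pm >= 3)
        or (ps == 1 and pm == 2 and pp >= 2)
        or (ps == 1 and pm == 1 and pp >= 4)
    )
    likely = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and pm in (1, 2))
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    if pathogenic:
        return "pathogenic"
    if likely:
        return "likely_pathogenic"
    if (benign or likely_benign) and p_side:
        return "uncertain_significance"
    if benign:
        return "benign"
    if likely_benign:
        return "likely_benign"
    return "uncertain_significance"


def chi2_2x2_oracle(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Textbook 2x2 Pearson chi-square with optional Yates correction."""
    n = a + b + c + d
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2.0)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    stat = n * num**2 / denom
    return stat, float(chi2_dist.sf(stat, 1))


def hwe_oracle(n_rr: int, n_ra: int, n_aa: int) -> tuple[float, float]:
    """Goodness-of-fit HWE chi-square from first principles."""
    n = n_rr + n_ra + n_aa
    q = (n_ra + 2 * n_aa) / (2 * n)
    p = 1 - q
    expected = [n * p * p, 2 * n * p * q, n * q * q]
    observed = [n_rr, n_ra, n_aa]
    stat = sum((o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0)
    return stat, float(chi2_dist.sf(stat, 1))


def average_precision_oracle(scores, labels) -> float:
    """AP by literal threshold enumeration, ties grouped."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        mask = scores >= t
        tp = int(labels[mask].sum())
        precision = tp / int(mask.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def filter_a_oracle(v, maf_threshold=0.01, missing_passes=True, splice_cutoff=0.6, min_votes=3) -> bool:
    """Literal conjunction of the Filter A retention rules."""
    rare = (v.maf_global is None and missing_passes) or (
        v.maf_global is not None and v.maf_global <= maf_threshold
    )
    if not rare:
        return False
    if v.effect_class in ("nonsense", "frameshift"):
        return True
    if v.effect_class == "splice_site":
        best = max(
            [s for s in (v.ada_score, v.rf_score) if s is not None], default=None
        )
        return best is not None and best >= splice_cutoff
    if v.effect_class == "inframe_indel":
        return True
    if v.effect_class == "missense":
        votes = sum(1 for c in v.predictor_calls.values() if c == "deleterious")
        return votes >= min_votes
    return False
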