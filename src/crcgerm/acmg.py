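"""ACMG/AMP evidence-combining engine.

Evidence codes are the standard tokens (PVS1; PS1-PS4; PM1-PM6; PP1-PP5;
BA1; BS1-BS4; BP1-BP7), each carrying a fixed strength class given by its
prefix. ``classify`` applies the published combining rules to produce one
of the five classes: pathogenic, likely pathogenic, uncertain significance,
likely benign, benign.

Two conflict policies are supported. Clinical practice frequently reports
a pathogenic verdict even when an isolated benign-supporting code is
present; ``override_bp`` (the default) keeps the pathogenic-side verdict
and flags the conflict, while ``strict_vus`` demotes any mixed evidence
set to uncertain significance, the guideline's conservative reading.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ALL_CODES",
    "EvidenceSet",
    "ClassificationResult",
    "parse_criteria",
    "classify",
    "strength_class",
]

_CODE_RE = re.compile(r"^(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])$")

ALL_CODES: tuple[str, ...] = (
    ("PVS1",)
    + tuple(f"PS{i}" for i in range(1, 5))
    + tuple(f"PM{i}" for i in range(1, 7))
    + tuple(f"PP{i}" for i in range(1, 6))
    + ("BA1",)
    + tuple(f"BS{i}" for i in range(1, 5))
    + tuple(f"BP{i}" for i in range(1, 8))
)

PATHOGENIC_SIDE = frozenset(c for c in ALL_CODES if c[0] == "P")
BENIGN_SIDE = frozenset(c for c in ALL_CODES if c[0] == "B")

CONFLICT_POLICIES = ("override_bp", "strict_vus")

VERDICTS = (
    "pathogenic",
    "likely_pathogenic",
    "uncertain_significance",
    "likely_benign",
    "benign",
)


def strength_class(code: str) -> str:
    """Strength prefix of a validated code: PVS, PS, PM, PP, BA, BS or BP."""
    if code == "PVS1":
        return "PVS"
    if code == "BA1":
        return "BA"
    return code[:2]


@dataclass(frozen=True)
class EvidenceSet:
    """A set of distinct, validated evidence codes."""

    codes: frozenset[str]

    def __post_init__(self) -> None:
        for code in self.codes:
            if not _CODE_RE.match(code):
                raise ValueError(f"invalid evidence code: {code!r}")

    def count(self, strength: str) -> int:
        return sum(1 for c in self.codes if strength_class(c) == strength)

    @property
    def has_pathogenic_side(self) -> bool:
        return bool(self.codes & PATHOGENIC_SIDE)

    @property
    def has_benign_side(self) -> bool:
        return bool(self.codes & BENIGN_SIDE)


@dataclass(frozen=True)
class ClassificationResult:
    verdict: str
    rule_fired: str
    conflict: bool


def parse_criteria(text: str) -> EvidenceSet:
    """Parse a criteria string like ``"PVS1 + PM2 + PM4"`` into an EvidenceSet.

    Tokens are separated by ``+`` with arbitrary surrounding whitespace.
    An empty string yields the empty evidence set.
    """
    tokens = [t.strip() for t in text.split("+")] if text.strip() else []
    codes: set[str] = set()
    for tok in tokens:
        if not _CODE_RE.match(tok):
            raise ValueError(f"unrecognised ACMG/AMP evidence token: {tok!r}")
        codes.add(tok)
    return EvidenceSet(frozenset(codes))


def _pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        return "P:PVS1+support"
    if ps >= 2:
        return "P:>=2PS"
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return "P:1PS+moderate"
    return None


def _likely_pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs >= 1 and pm == 1:
        return "LP:PVS1+1PM"
    if ps == 1 and 1 <= pm <= 2:
        return "LP:1PS+1-2PM"
    if ps == 1 and pp >= 2:
        return "LP:1PS+>=2PP"
    if pm >= 3:
        return "LP:>=3PM"
    if pm == 2 and pp >= 2:
        return "LP:2PM+>=2PP"
    if pm == 1 and pp >= 4:
        return "LP:1PM+>=4PP"
    return None


def _benign_rule(ba: int, bs: int, bp: int) -> tuple[str, str] | None:
    if ba >= 1:
        return "benign", "B:BA1"
    if bs >= 2:
        return "benign", "B:>=2BS"
    if bs == 1 and bp >= 1:
        return "likely_benign", "LB:1BS+1BP"
    if bp >= 2:
        return "likely_benign", "LB:>=2BP"
    return None


def classify(ev: EvidenceSet, conflict_policy: str = "override_bp") -> ClassificationResult:
    """Combine an evidence set into a five-class verdict.

    Pathogenic-side combinations are evaluated on the P-side codes alone;
    benign-side combinations on the B-side codes alone. When both sides
    would fire, ``override_bp`` keeps the pathogenic-side verdict and marks
    ``conflict=True``; ``strict_vus`` returns uncertain significance for
    any co-occurrence of pathogenic- and benign-side evidence.
    """
    if conflict_policy not in CONFLICT_POLICIES:
        raise ValueError(f"unknown conflict policy: {conflict_policy!r}")

    pvs = ev.count("PVS")
    ps = ev.count("PS")
    pm = ev.count("PM")
    pp = ev.count("PP")
    ba = ev.count("BA")
    bs = ev.count("BS")
    bp = ev.count("BP")

    conflict = ev.has_pathogenic_side and ev.has_benign_side

    p_rule = _pathogenic_rule(pvs, ps, pm, pp)
    lp_rule = _likely_pathogenic_rule(pvs, ps, pm, pp)
    b_result = _benign_rule(ba, bs, bp)

    if conflict and conflict_policy == "strict_vus":
        return ClassificationResult("uncertain_significance", "VUS:conflict", True)

    if p_rule:
        return ClassificationResult("pathogenic", p_rule, conflict)
    if lp_rule:
        return ClassificationResult("likely_pathogenic", lp_rule, conflict)
    if b_result and not conflict:
        verdict, rule = b_result
        return ClassificationResult(verdict, rule, False)
    if b_result and conflict:
        # P-side evidence present but insufficient for P/LP; B-side fires.
        # Under override_bp a benign verdict with opposing evidence is still
        # demoted to VUS, matching the guideline treatment of mixed sets.
        return ClassificationResult("uncertain_significance", "VUS:conflict", True)
    return ClassificationResult("uncertain_significance", "VUS:insufficient", conflict)
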