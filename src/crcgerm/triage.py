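"""Filter A: rarity filtering, effect routing, splice-score gating and
missense predictor voting.

The filter retains rare variants (global MAF at or below 1% by default;
variants absent from the population databases pass, since truly novel
variants have no recorded frequency) and routes them by effect class:

* nonsense / frameshift / splice-site -> loss-of-function route; canonical
  splice-site variants additionally require support from the dbscSNV-style
  ensemble scores (ADA / RF, cut-off 0.6, either score suffices by default);
* missense -> retained when at least 3 of the 6 in-silico predictors call
  the variant deleterious (missing calls count against, keeping the
  denominator at six);
* in-frame indels -> retained on rarity alone;
* synonymous and everything else -> excluded.

Variants surviving the filter are the candidates handed to the ACMG/AMP
classification engine.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .models import AnnotatedVariant, LOF_EFFECTS

__all__ = [
    "TriageConfig",
    "TriageDecision",
    "passes_maf",
    "splice_gate",
    "missense_vote",
    "filter_a",
]


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds and policies for Filter A.

    ``splice_require_both`` switches the ADA/RF gate from "either score at
    or above the cut-off" (the default, favouring sensitivity) to
    "every available score at or above it".
    """

    maf_threshold: float = 0.01
    maf_missing_passes: bool = True
    splice_cutoff: float = 0.6
    splice_require_both: bool = False
    min_votes: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold <= 1.0:
            raise ValueError("maf_threshold must lie in (0, 1]")
        if not 0.0 <= self.splice_cutoff <= 1.0:
            raise ValueError("splice_cutoff must lie in [0, 1]")
        if not 0 <= self.min_votes <= 6:
            raise ValueError("min_votes must lie in 0..6")


@dataclass(frozen=True)
class TriageDecision:
    variant: AnnotatedVariant
    retained: bool
    route: str  # lof | splice | missense | inframe | excluded
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.retained != (self.route != "excluded"):
            raise ValueError("retained must be false exactly when route is 'excluded'")
        if not self.retained and not self.reasons:
            raise ValueError("an excluded decision must carry at least one reason")


def passes_maf(
    v: AnnotatedVariant,
    threshold: float = 0.01,
    missing_passes: bool = True,
) -> bool:
    """Rarity gate: global MAF <= threshold, inclusive; missing MAF passes
    when ``missing_passes`` (novel variants have no database frequency)."""
    if v.maf_global is None:
        return missing_passes
    return v.maf_global <= threshold


def splice_gate(
    ada: float | None,
    rf: float | None,
    cutoff: float = 0.6,
    require_both: bool = False,
) -> bool:
    """Splice-impact gate on the ADA/RF ensemble scores, inclusive cut-off.

    With ``require_both`` false (default) the gate passes when the best
    available score meets the cut-off; with it true, every available score
    must. Both scores missing never passes: no evidence of splice impact.
    """
    scores = [s for s in (ada, rf) if s is not None]
    if not scores:
        return False
    if require_both:
        return min(scores) >= cutoff
    return max(scores) >= cutoff


def missense_vote(predictor_calls: dict[str, str], min_positive: int = 3) -> bool:
    """Predictor vote: at least ``min_positive`` of the six in-silico
    predictors call the variant deleterious; missing calls do not count."""
    positive = sum(1 for call in predictor_calls.values() if call == "deleterious")
    return positive >= min_positive


def triage_one(v: AnnotatedVariant, config: TriageConfig = TriageConfig()) -> TriageDecision:
    """Apply Filter A to a single variant."""
    reasons: list[str] = []
    if not passes_maf(v, config.maf_threshold, config.maf_missing_passes):
        return TriageDecision(v, False, "excluded", ("maf_above_threshold",))

    if v.effect_class in LOF_EFFECTS:
        if v.effect_class == "splice_site":
            if splice_gate(v.ada_score, v.rf_score, config.splice_cutoff, config.splice_require_both):
                return TriageDecision(v, True, "splice", ("lof_effect", "splice_scores_pass"))
            return TriageDecision(v, False, "excluded", ("splice_scores_fail",))
        return TriageDecision(v, True, "lof", ("lof_effect",))

    if v.effect_class == "inframe_indel":
        return TriageDecision(v, True, "inframe", ("inframe_effect",))

    if v.effect_class == "missense":
        if missense_vote(v.predictor_calls, config.min_votes):
            return TriageDecision(v, True, "missense", ("predictor_vote_pass",))
        return TriageDecision(v, False, "excluded", ("predictor_vote_fail",))

    reasons.append(f"effect_not_considered:{v.effect_class}")
    return TriageDecision(v, False, "excluded", tuple(reasons))


def filter_a(
    variants: Iterable[AnnotatedVariant],
    config: TriageConfig = TriageConfig(),
) -> list[TriageDecision]:
    """Apply Filter A to a cohort; output is a partition of the input."""
    return [triage_one(v, config) for v in variants]


def gate_counts(decisions: Sequence[TriageDecision]) -> dict[str, int]:
    """Tally of variants per route plus exclusion reasons, for reporting
    counts at each gate of the filter."""
    counts: dict[str, int] = {"input": len(decisions)}
    for d in decisions:
        counts[f"route:{d.route}"] = counts.get(f"route:{d.route}", 0) + 1
        if not d.retained:
            for r in d.reasons:
                counts[f"excluded:{r}"] = counts.get(f"excluded:{r}", 0) + 1
    counts["retained"] = sum(1 for d in decisions if d.retained)
    return counts
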