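"""Filter A: rarity gate, splice-score gate, predictor vote, routing."""

import numpy as np
import pytest

from crcgerm.models import PREDICTORS, AnnotatedVariant
from crcgerm.triage import (
    TriageConfig,
    TriageDecision,
    filter_a,
    gate_counts,
    missense_vote,
    passes_maf,
    splice_gate,
)

from .oracles import filter_a_oracle


def make_variant(**kw):
    base = dict(chrom="chr1", pos=100, ref="A", alt="T", gene="APC")
    base.update(kw)
    return AnnotatedVariant(**base)


def calls(n_deleterious, n_tolerated=None):
    out = {}
    for i, p in enumerate(PREDICTORS):
        if i < n_deleterious:
            out[p] = "deleterious"
        elif n_tolerated is None or i < n_deleterious + n_tolerated:
            out[p] = "tolerated"
        else:
            out[p] = "missing"
    return out


class TestMafGate:
    def test_above_threshold_fails(self):
        assert not passes_maf(make_variant(maf_global=0.02), 0.01)

    def test_missing_maf_passes_by_default(self):
        assert passes_maf(make_variant(maf_global=None), 0.01, missing_passes=True)
        assert not passes_maf(make_variant(maf_global=None), 0.01, missing_passes=False)

    def test_boundary_is_inclusive(self):
        assert passes_maf(make_variant(maf_global=0.01), 0.01)


class TestSpliceGate:
    @pytest.mark.parametrize(
        "ada,rf,expected",
        [(0.95, 0.40, True), (None, None, False), (0.6, 0.6, True), (0.59, None, False)],
    )
    def test_max_rule(self, ada, rf, expected):
        assert splice_gate(ada, rf, 0.6) is expected

    def test_require_both(self):
        assert splice_gate(0.95, 0.40, 0.6, require_both=True) is False
        assert splice_gate(0.95, None, 0.6, require_both=True) is True
        assert splice_gate(0.7, 0.65, 0.6, require_both=True) is True


class TestMissenseVote:
    @pytest.mark.parametrize(
        "n_del,n_tol,expected",
        [(3, 3, True), (2, 0, False), (6, 0, True), (0, 0, False)],
    )
    def test_vote_counting(self, n_del, n_tol, expected):
        assert missense_vote(calls(n_del, n_tol), 3) is expected

    def test_missing_counts_against(self):
        # 2 deleterious + 4 missing stays below a threshold of 3
        assert not missense_vote(calls(2, 0), 3)


class TestFilterA:
    def test_novel_frameshift_retained_on_lof_route(self):
        [d] = filter_a([make_variant(effect_class="frameshift", maf_global=None)])
        assert d.retained and d.route == "lof"

    def test_missense_failing_vote_excluded(self):
        [d] = filter_a(
            [make_variant(effect_class="missense", predictor_calls=calls(1, 5), maf_global=0.001)]
        )
        assert not d.retained and "predictor_vote_fail" in d.reasons

    def test_rare_synonymous_excluded(self):
        [d] = filter_a([make_variant(effect_class="synonymous", maf_global=0.001)])
        assert not d.retained

    def test_splice_site_requires_score_support(self):
        passing = make_variant(effect_class="splice_site", ada_score=0.9, maf_global=None)
        failing = make_variant(effect_class="splice_site", ada_score=0.1, rf_score=0.2, maf_global=None)
        d_pass, d_fail = filter_a([passing, failing])
        assert d_pass.retained and d_pass.route == "splice"
        assert not d_fail.retained

    def test_output_is_a_partition(self, cohort_seed1):
        variants, _, _ = cohort_seed1
        decisions = filter_a(variants)
        assert len(decisions) == len(variants)
        assert [d.variant for d in decisions] == list(variants)
        counts = gate_counts(decisions)
        route_total = sum(v for k, v in counts.items() if k.startswith("route:"))
        assert route_total == counts["input"]

    def test_decision_invariants_enforced(self):
        with pytest.raises(ValueError):
            TriageDecision(make_variant(), retained=False, route="excluded", reasons=())
        with pytest.raises(ValueError):
            TriageDecision(make_variant(), retained=True, route="excluded", reasons=("x",))


def _random_variants(n, seed):
    rng = np.random.default_rng(seed)
    effects = ["missense", "nonsense", "frameshift", "splice_site", "inframe_indel", "synonymous", "other"]
    out = []
    for i in range(n):
        n_del = int(rng.integers(0, 7))
        out.append(
            make_variant(
                pos=100 + i,
                effect_class=effects[int(rng.integers(len(effects)))],
                maf_global=None if rng.random() < 0.2 else float(rng.random() * 0.05),
                ada_score=None if rng.random() < 0.4 else float(rng.random()),
                rf_score=None if rng.random() < 0.4 else float(rng.random()),
                predictor_calls=calls(n_del, 6 - n_del),
            )
        )
    return out


def test_filter_matches_literal_rule_conjunction_oracle():
    variants = _random_variants(1000, seed=77)
    decisions = filter_a(variants)
    for v, d in zip(variants, decisions):
        assert d.retained == filter_a_oracle(v), v


def test_monotonicity_in_thresholds():
    """Tightening the MAF threshold or the vote minimum never retains a
    variant that the looser setting excluded."""
    variants = _random_variants(400, seed=11)
    loose = {id(d.variant) for d in filter_a(variants, TriageConfig(maf_threshold=0.01)) if d.retained}
    tight = {id(d.variant) for d in filter_a(variants, TriageConfig(maf_threshold=0.001)) if d.retained}
    assert tight <= loose
    low_votes = {id(d.variant) for d in filter_a(variants, TriageConfig(min_votes=2)) if d.retained}
    high_votes = {id(d.variant) for d in filter_a(variants, TriageConfig(min_votes=5)) if d.retained}
    assert high_votes <= low_votes
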