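"""Precision-recall concordance between driver scores and pathogenicity labels."""

import itertools

import numpy as np
import pytest

from crcgerm.concordance import (
    ScoredVariantPair,
    SingleClassError,
    binarize_label,
    per_gene_auc,
    pr_auc,
    summarize_concordance,
)
from crcgerm.models import GenePanelEntry
from crcgerm.simulate import gen_score_pairs

from .oracles import average_precision_oracle


class TestBinarize:
    @pytest.mark.parametrize(
        "label,policy,expected",
        [
            ("ambiguous", "nonbenign_positive", "positive"),
            ("ambiguous", "pathogenic_only", "negative"),
            ("ambiguous", "exclude_ambiguous", "excluded"),
            ("likely_benign", "nonbenign_positive", "negative"),
            ("likely_benign", "pathogenic_only", "negative"),
            ("likely_pathogenic", "exclude_ambiguous", "positive"),
        ],
    )
    def test_policies(self, label, policy, expected):
        assert binarize_label(label, policy) == expected

    def test_rejects_unknown_inputs(self):
        with pytest.raises(ValueError):
            binarize_label("pathogenic", "nonbenign_positive")
        with pytest.raises(ValueError):
            binarize_label("ambiguous", "bogus")


class TestPrAuc:
    def test_three_point_worked_example(self):
        # ranks: 0.9 (pos, P=1/1), 0.8 (neg), 0.3 (pos, P=2/3); AP=(1+2/3)/2
        res = pr_auc([0.9, 0.8, 0.3], [1, 0, 1])
        assert res.auc == pytest.approx(5 / 6)
        assert res.n_pos == 2 and res.n_neg == 1

    def test_perfect_separation(self):
        res = pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)

    def test_uninformative_scores_converge_to_prevalence(self):
        rng = np.random.default_rng(42)
        n = 100_000
        labels = (rng.random(n) < 0.3).astype(int)
        scores = rng.random(n)
        res = pr_auc(scores, labels)
        assert res.auc == pytest.approx(labels.mean(), abs=0.01)

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            pr_auc([0.1, 0.9], [1, 1])

    def test_recall_nondecreasing_and_auc_bounded(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        res = pr_auc(scores, labels)
        assert all(b >= a for a, b in zip(res.recall_points, res.recall_points[1:]))
        assert 0.0 <= res.auc <= 1.0

    def test_matches_threshold_enumeration_oracle(self):
        """AP equals literal threshold enumeration, including tied scores."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.sum() in (0, n):
                continue
            assert pr_auc(scores, labels).auc == pytest.approx(
                average_precision_oracle(scores, labels)
            )

    def test_exhaustive_label_assignments_small_n(self):
        """With distinct scores, AP agrees with the oracle for every label
        assignment at n<=8, and flipping labels with reversed scores is the
        oracle of its own input."""
        scores = np.linspace(0.1, 0.8, 8)
        for labels in itertools.product([0, 1], repeat=8):
            y = np.array(labels)
            if y.sum() in (0, 8):
                continue
            assert pr_auc(scores, y).auc == pytest.approx(average_precision_oracle(scores, y))
            flipped = 1 - y
            assert pr_auc(1 - scores, flipped).auc == pytest.approx(
                average_precision_oracle(1 - scores, flipped)
            )

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(100)
        labels = (rng.random(100) < 0.4).astype(int)
        base = pr_auc(scores, labels).auc
        assert pr_auc(scores**3, labels).auc == pytest.approx(base)
        assert pr_auc(1 - np.exp(-5 * scores), labels).auc == pytest.approx(base)

    def test_trapezoid_estimator_available(self):
        res = pr_auc([0.9, 0.8, 0.3], [1, 0, 1], estimator="trapezoid")
        assert 0.0 <= res.auc <= 1.0


class TestPerGene:
    def test_mean_over_tumor_types(self):
        pairs = gen_score_pairs((50, 50), seed=1, gene="A", tumor_type="T1")
        pairs += gen_score_pairs((50, 50), seed=2, gene="A", tumor_type="T2")
        single = {
            "T1": pr_auc(
                [p.score for p in pairs if p.tumor_type == "T1"],
                [1 if p.label_class == "likely_pathogenic" else 0 for p in pairs if p.tumor_type == "T1"],
            ).auc,
            "T2": pr_auc(
                [p.score for p in pairs if p.tumor_type == "T2"],
                [1 if p.label_class == "likely_pathogenic" else 0 for p in pairs if p.tumor_type == "T2"],
            ).auc,
        }
        result = per_gene_auc(pairs)
        assert result["A"] == pytest.approx(np.mean(list(single.values())))

    def test_single_class_stratum_dropped(self, caplog):
        pairs = gen_score_pairs((40, 40), seed=3, gene="A", tumor_type="T1")
        pairs += [ScoredVariantPair("A", "T2", 0.9, "likely_pathogenic")] * 5
        only_t1 = per_gene_auc(pairs[:80])
        both = per_gene_auc(pairs)
        assert both["A"] == pytest.approx(only_t1["A"])

    def test_gene_without_valid_stratum_omitted(self):
        pairs = [ScoredVariantPair("B", "T1", 0.9, "likely_pathogenic")] * 4
        assert per_gene_auc(pairs) == {}

    def test_planted_separability_recovered(self):
        """Beta(8,2) vs Beta(2,8) class-conditional scores at n=10^4 per
        class recover the pinned Monte-Carlo AP of 0.998 within 0.02."""
        pairs = gen_score_pairs((10_000, 10_000), (8, 2), (2, 8), seed=4)
        assert per_gene_auc(pairs)["GENE1"] == pytest.approx(0.998, abs=0.02)

    def test_ap_increases_with_separation(self):
        aucs = []
        for a in (2.0, 4.0, 6.0, 8.0, 12.0):
            pairs = gen_score_pairs((2000, 2000), (a, 2.0), (2.0, a), seed=10)
            aucs.append(per_gene_auc(pairs)["GENE1"])
        assert aucs == sorted(aucs)


class TestSummary:
    def test_overall_and_extremes(self):
        summary = summarize_concordance({"A": 0.6, "B": 0.8, "C": 1.0})
        assert summary["overall_mean_auc"] == pytest.approx(0.8)
        assert summary["min_auc"] == 0.6 and summary["max_auc"] == 1.0

    def test_panel_subset_mean(self):
        panel = [GenePanelEntry("B", "diagnostic", "high")]
        summary = summarize_concordance({"A": 0.6, "B": 0.8}, panel)
        assert summary["panel_mean_auc"] == pytest.approx(0.8)
        assert summary["n_panel_genes"] == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_concordance({})
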