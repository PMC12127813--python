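"""Concordance benchmarking of driver scores against three-class missense
pathogenicity labels.

For every (gene, tumour type) stratum the three-class label is binarised
(default: benign vs non-benign, i.e. ambiguous counts as positive), a
precision-recall curve is built over the driver scores, and its area is
summarised per gene as the unweighted mean over tumour types, then over
genes overall and restricted to a gene panel.

The default area estimator is step-wise average precision (ties grouped),
AP = sum_k (R_k - R_{k-1}) P_k; trapezoidal interpolation of the curve is
available but linear interpolation in PR space is optimistically biased
and is therefore not the default.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from .models import AM_CLASSES, GenePanelEntry

__all__ = [
    "ScoredVariantPair",
    "PRResult",
    "binarize_label",
    "pr_auc",
    "per_gene_auc",
    "summarize_concordance",
]

logger = logging.getLogger(__name__)

BINARIZE_POLICIES = ("nonbenign_positive", "pathogenic_only", "exclude_ambiguous")
ESTIMATORS = ("step_average_precision", "trapezoid")


@dataclass(frozen=True)
class ScoredVariantPair:
    """One joined (driver score, pathogenicity label) observation."""

    gene: str
    tumor_type: str
    score: float
    label_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
        if self.label_class not in AM_CLASSES:
            raise ValueError(f"unknown label class: {self.label_class!r}")


@dataclass(frozen=True)
class PRResult:
    recall_points: tuple[float, ...]
    precision_points: tuple[float, ...]
    auc: float
    n_pos: int
    n_neg: int


class SingleClassError(ValueError):
    """A precision-recall curve is undefined without both classes."""


def binarize_label(label_class: str, policy: str = "nonbenign_positive") -> str:
    """Map a three-class label to positive / negative / excluded.

    ``nonbenign_positive`` (default): the benchmark separates benign from
    non-benign, so ambiguous joins the positive class. ``pathogenic_only``
    sends ambiguous to the negatives; ``exclude_ambiguous`` drops it.
    """
    if policy not in BINARIZE_POLICIES:
        raise ValueError(f"unknown binarization policy: {policy!r}")
    if label_class not in AM_CLASSES:
        raise ValueError(f"unknown label class: {label_class!r}")
    if label_class == "likely_benign":
        return "negative"
    if label_class == "likely_pathogenic":
        return "positive"
    return {
        "nonbenign_positive": "positive",
        "pathogenic_only": "negative",
        "exclude_ambiguous": "excluded",
    }[policy]


def pr_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    estimator: str = "step_average_precision",
) -> PRResult:
    """Precision-recall curve and area for binary labels ranked by score.

    Tied scores are grouped into single thresholds. Raises
    ``SingleClassError`` when only one class is present.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator: {estimator!r}")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("scores and labels must be parallel 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError(
            f"precision-recall curve undefined: {n_pos} positives, {n_neg} negatives"
        )
    precision, recall, _ = precision_recall_curve(y, s)
    # sklearn returns the curve from high threshold to low; flip so recall
    # is non-decreasing along the returned points.
    precision = precision[::-1]
    recall = recall[::-1]
    if estimator == "step_average_precision":
        auc = float(average_precision_score(y, s))
    else:
        auc = float(np.trapezoid(precision, recall))
    return PRResult(
        recall_points=tuple(float(r) for r in recall),
        precision_points=tuple(float(p) for p in precision),
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _binarized_frame(
    pairs: Iterable[ScoredVariantPair], policy: str
) -> pd.DataFrame:
    rows = []
    for p in pairs:
        b = binarize_label(p.label_class, policy)
        if b == "excluded":
            continue
        rows.append((p.gene, p.tumor_type, p.score, 1 if b == "positive" else 0))
    return pd.DataFrame(rows, columns=["gene", "tumor_type", "score", "label"])


def per_gene_auc(
    pairs: Iterable[ScoredVariantPair],
    policy: str = "nonbenign_positive",
    estimator: str = "step_average_precision",
    weight_by_count: bool = False,
) -> dict[str, float]:
    """Per-gene PR-AUC, averaged over tumour types.

    Each (gene, tumour type) stratum contributes one AUC; strata with a
    single class are dropped with a warning. The per-gene value is the
    unweighted mean over surviving strata (or variant-count-weighted when
    requested); genes with no valid stratum are omitted.
    """
    df = _binarized_frame(pairs, policy)
    out: dict[str, float] = {}
    for gene, gdf in df.groupby("gene", sort=True):
        aucs: list[float] = []
        weights: list[int] = []
        for tt, tdf in gdf.groupby("tumor_type", sort=True):
            try:
                res = pr_auc(tdf["score"].to_numpy(), tdf["label"].to_numpy(), estimator)
            except SingleClassError:
                logger.warning("dropping single-class stratum (%s, %s)", gene, tt)
                continue
            aucs.append(res.auc)
            weights.append(len(tdf))
        if not aucs:
            logger.warning("gene %s has no stratum with both classes; omitted", gene)
            continue
        if weight_by_count:
            out[str(gene)] = float(np.average(aucs, weights=weights))
        else:
            out[str(gene)] = float(np.mean(aucs))
    return out


def summarize_concordance(
    gene_aucs: dict[str, float],
    panel: Sequence[GenePanelEntry] = (),
) -> dict:
    """Overall and panel-restricted summary of per-gene AUCs."""
    if not gene_aucs:
        raise ValueError("no genes with a defined AUC to summarize")
    values = np.array(list(gene_aucs.values()), dtype=float)
    panel_symbols = {e.symbol for e in panel}
    panel_values = [a for g, a in gene_aucs.items() if g in panel_symbols]
    return {
        "n_genes": len(gene_aucs),
        "overall_mean_auc": float(values.mean()),
        "min_auc": float(values.min()),
        "max_auc": float(values.max()),
        "n_panel_genes": len(panel_values),
        "panel_mean_auc": float(np.mean(panel_values)) if panel_values else None,
    }
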