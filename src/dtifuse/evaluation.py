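"""Evaluation: classification metrics, ranking metrics, paired testing,
and the k-fold cross-validation driver.

AUROC is computed as the Mann-Whitney probability that a random positive
outscores a random negative (ties counted 1/2).  AUPRC uses step-wise
average-precision integration (sum over recall increments of the precision
at each score threshold), which avoids the optimism of trapezoidal
interpolation.  The Wilcoxon signed-rank test is exact (dynamic-programming
enumeration of sign assignments over the rank sum) for n <= 25 after
dropping zero differences, with a tie-corrected normal approximation above.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import FusionModel, TrainingConfig
from .splits import FoldAssignment, audit_leakage

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "classification_metrics",
    "auroc",
    "auprc",
    "wilcoxon_signed_rank",
    "cross_validate",
    "CrossValidationResult",
    "METRICS",
]

METRICS = ("auroc", "auprc", "f_measure", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R), accuracy.

    Degenerate denominators yield 0 (and F is 0 when P + R = 0).
    """
    if counts.total == 0:
        raise ValueError("no evaluated pairs")
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f_measure = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    accuracy = (counts.tp + counts.tn) / counts.total
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
        "accuracy": accuracy,
    }


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def auprc(scores, labels) -> float:
    """Average-precision AUPRC: sum over recall increments of precision at
    each distinct score threshold (descending)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("at least one positive required")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # threshold boundaries: last index of each distinct score
    distinct = np.where(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    n_at = cut + 1
    precision = tp / n_at
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def _exact_wplus_sf(ranks2: np.ndarray) -> np.ndarray:
    """Counts of achievable W+ (over doubled ranks) across all 2^n sign
    assignments, via polynomial convolution."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    a, b, alternative: Literal["two-sided", "greater", "less"] = "two-sided"
) -> float:
    """p-value of the Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; ``greater`` tests whether ``a`` tends to
    exceed ``b``.  Exact for n <= 25, normal approximation (tie-corrected,
    continuity-corrected) above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("samples must be paired and non-empty")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1.0")
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        counts = _exact_wplus_sf(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
    else:
        mean = n * (n + 1) / 4
        var = n * (n + 1) * (2 * n + 1) / 24
        # tie correction
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48
        sd = np.sqrt(var)
        from scipy.stats import norm

        p_ge = norm.sf((w_plus - 0.5 - mean) / sd)
        p_le = norm.cdf((w_plus + 0.5 - mean) / sd)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))


@dataclass
class CrossValidationResult:
    """Per-fold metric table with mean and population SD, plus the
    per-fold test predictions retained for paired model comparison."""

    table: pd.DataFrame
    predictions: list[pd.DataFrame] = field(repr=False, default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.table[list(METRICS)].mean()

    @property
    def sd(self) -> pd.Series:
        return self.table[list(METRICS)].std(ddof=0)

    def summary(self) -> str:
        lines = [self.table.to_string(index=False, float_format="%.4f")]
        lines.append(
            "mean ± SD: "
            + "  ".join(
                f"{m}={self.mean[m]:.4f}±{self.sd[m]:.4f}" for m in METRICS
            )
        )
        return "\n".join(lines)


def cross_validate(
    assignment: FoldAssignment,
    mode: str,
    config: TrainingConfig,
    *,
    sequences=None,
    fingerprints=None,
    protein_embeddings=None,
    compound_embeddings=None,
    verbose: bool = False,
) -> CrossValidationResult:
    """Train and evaluate one model per fold of a fold assignment.

    For hard splits the assignment is audited leakage-free before any
    training.  Metrics per test fold: AUROC, AUPRC, F-measure, accuracy at
    the configured decision threshold.
    """
    report = audit_leakage(assignment)
    if not report.passed:
        raise ValueError(
            f"fold assignment fails leakage audit: {report.detail} "
            f"({report.offending_entities[:5]})"
        )
    rows = []
    predictions = []
    for fold in range(assignment.k):
        train = assignment.train_pairs(fold)
        test = assignment.test_pairs(fold)
        model = FusionModel(
            train,
            mode=mode,
            sequences=sequences,
            fingerprints=fingerprints,
            protein_embeddings=protein_embeddings,
            compound_embeddings=compound_embeddings,
            config=config,
        )
        results = model.fit(verbose=verbose)
        scores, labels = results.predict(test)
        y = test.frame["label"].to_numpy()
        counts = ConfusionCounts.from_predictions(y, labels)
        cm = classification_metrics(counts)
        rows.append(
            {
                "fold": fold,
                "n_train": len(train),
                "n_test": len(test),
                "auroc": auroc(scores, y),
                "auprc": auprc(scores, y),
                "f_measure": cm["f_measure"],
                "accuracy": cm["accuracy"],
            }
        )
        pred = test.frame.copy()
        pred["score"] = scores
        pred["predicted"] = labels
        predictions.append(pred)
        logger.info("fold %d: %s", fold, rows[-1])
    return CrossValidationResult(table=pd.DataFrame(rows),
                                 predictions=predictions)
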