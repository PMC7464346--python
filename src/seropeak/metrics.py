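"""Diagnostic test metrics for the %-LOOCV score distributions.

Covers the equidistant-SD group cut-off, the confusion matrix and
sensitivity / specificity / efficiency, the RMS-denominator Cohen's d
effect size, and the rank-based ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestMetrics",
    "equidistant_cutoff",
    "cohens_d_rms",
    "confusion_and_metrics",
    "roc_auc",
]


@dataclass
class TestMetrics:
    """Confusion counts and derived test metrics at a score cut-off."""

    __test__ = False  # "Test" prefix is domain vocabulary, not a pytest class

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    efficiency: float
    tpr: float
    fpr: float
    cohens_d: float = np.nan
    auc: float = np.nan
    cutoff: float = np.nan
    k_sd: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TestMetrics":
        return cls(**d)


def equidistant_cutoff(
    mean_hi: float, sd_hi: float, mean_lo: float, sd_lo: float
) -> tuple[float, float]:
    """Score cut-off lying an equal number of group-specific SDs below the
    high-scoring group mean and above the low-scoring group mean.

    Solves ``mean_hi - k*sd_hi = mean_lo + k*sd_lo`` for the SD multiplier
    ``k = (mean_hi - mean_lo) / (sd_hi + sd_lo)``; the cut-off is evaluated
    with the exact multiplier so both distances agree, then ``k`` and the
    cut-off are reported rounded to two decimals. When both SDs are zero the
    cut-off degrades to the midpoint of the means and ``k`` is NaN.

    Downstream rule: score > cutoff -> high-scoring group; score <= cutoff
    -> low-scoring group.

    Returns
    -------
    (k_sd, cutoff)
    """
    if mean_hi <= mean_lo:
        raise ValueError("mean_hi must exceed mean_lo")
    denom = sd_hi + sd_lo
    if denom == 0:
        return float("nan"), round((mean_hi + mean_lo) / 2.0, 2)
    k = (mean_hi - mean_lo) / denom
    cutoff = mean_hi - k * sd_hi  # == mean_lo + k * sd_lo
    return round(k, 2), round(cutoff, 2)


def cohens_d_rms(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with the root-mean-square of the two SDs as denominator:

        d = |mean1 - mean2| / sqrt((sd1^2 + sd2^2) / 2)
    """
    if sd1 == 0 and sd2 == 0:
        raise ValueError("Cohen's d undefined when both SDs are zero")
    return abs(mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def confusion_and_metrics(
    scores: pd.Series, labels: pd.Series, cutoff: float, disease_label
) -> TestMetrics:
    """Confusion counts and test metrics at ``cutoff``.

    A sample is called disease when its score is strictly above the cut-off;
    scores at or below it are called non-disease. Sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), efficiency (accuracy) = (TP+TN)/N.
    """
    labels = labels.reindex(scores.index)
    present = set(labels.unique())
    if disease_label not in present or len(present) < 2:
        raise ValueError("both disease and control labels must be present")
    is_disease = (labels == disease_label).to_numpy()
    called = scores.to_numpy() > cutoff
    tp = int(np.sum(is_disease & called))
    fn = int(np.sum(is_disease & ~called))
    fp = int(np.sum(~is_disease & called))
    tn = int(np.sum(~is_disease & ~called))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return TestMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        efficiency=(tp + tn) / (tp + tn + fp + fn),
        tpr=sens,
        fpr=1.0 - spec,
        cutoff=float(cutoff),
    )


def roc_auc(scores_disease, scores_control) -> float:
    """Probability that a random disease score exceeds a random control
    score, ties counting one half (the Mann-Whitney / rank-sum AUC)."""
    x = np.asarray(scores_disease, dtype=float)
    y = np.asarray(scores_control, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u = r1 - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))
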