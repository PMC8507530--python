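"""ROC/AUC evaluation of single features and miRNA-mRNA ratio features.

AUC equals the Mann-Whitney U statistic over (tumor, normal) sample pairs
divided by n_pos * n_neg, with ties half-credited; the tumor group (TT)
is the positive class throughout.  Markers reduced in tumors give raw
AUC < 0.5; the curve is then flipped and the orientation recorded, so a
good "down" marker still reports its discriminative AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "roc_auc", "pair_ratio_feature"]


@dataclass
class RocResult:
    feature_label: str
    auc: float
    orientation: str  # as_is | flipped
    thresholds: list[float] = field(default_factory=list)
    sensitivity: list[float] = field(default_factory=list)
    specificity: list[float] = field(default_factory=list)
    n_pos: int = 0
    n_neg: int = 0


def roc_auc(values, labels, feature_label: str = "") -> RocResult:
    """ROC curve and AUC for one scoring feature.

    ``labels`` are 'TT' (positive) / 'NNT' (negative).  AUC is the
    trapezoidal area over all distinct thresholds, identical to the
    tie-half-credited Mann-Whitney pair count.  If the raw AUC < 0.5 the
    scores are negated, the curve recomputed and orientation='flipped'.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray([1 if g == "TT" else 0 for g in labels])
    if not np.all(np.isfinite(v)):
        raise ValueError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")

    def curve(scores):
        fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
        # trapezoidal area; equals tie-adjusted U / (n_pos * n_neg)
        return float(np.trapezoid(tpr, fpr)), fpr, tpr, thr

    auc, fpr, tpr, thr = curve(v)
    orientation = "as_is"
    if auc < 0.5:
        auc, fpr, tpr, thr = curve(-v)
        orientation = "flipped"
    return RocResult(
        feature_label=feature_label,
        auc=auc,
        orientation=orientation,
        thresholds=[float(t) for t in thr],
        sensitivity=[float(t) for t in tpr],
        specificity=[float(1.0 - f) for f in fpr],
        n_pos=n_pos,
        n_neg=n_neg,
    )


def pair_ratio_feature(
    mirna_neg_dct,
    mrna_neg_dct,
    epsilon: float = 1e-6,
    mode: str = "ratio",
) -> tuple[np.ndarray, np.ndarray]:
    """Combine a miRNA and an mRNA -dCT profile into one score per sample.

    mode='ratio' divides (-dCT miRNA) / (-dCT mRNA), excluding samples
    whose denominator is within epsilon of zero (the -dCT scale crosses
    zero, so the ratio is a hazard there); mode='difference' subtracts
    instead, which is monotone and needs no guard.  Returns
    (scores, kept-sample boolean mask); raises if every sample is
    excluded.
    """
    num = np.asarray(mirna_neg_dct, dtype=float)
    den = np.asarray(mrna_neg_dct, dtype=float)
    if num.shape != den.shape:
        raise ValueError("miRNA and mRNA profiles must cover the same samples")
    if mode == "difference":
        return num - den, np.ones_like(num, dtype=bool)
    if mode != "ratio":
        raise ValueError(f"unknown mode {mode!r}")
    keep = np.abs(den) >= epsilon
    if not keep.any():
        raise ValueError("all samples excluded: denominator ~ 0 everywhere")
    scores = np.full_like(num, np.nan)
    scores[keep] = num[keep] / den[keep]
    return scores, keep
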