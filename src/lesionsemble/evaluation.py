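"""Segmentation quality metrics and method comparison.

Per-image metrics are the pixelwise Dice score, Jaccard index, sensitivity
and specificity of a predicted binary mask against ground truth (foreground
= 1 is the positive class).  Method-level comparisons use Welch's two-sample
t-test on per-image Dice scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts; foreground (1) is the positive class."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes must match")
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice score 2|A ∩ G| / (|A| + |G|); two empty masks agree perfectly."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes must match")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        logger.info("both masks empty: Dice defined as 1")
        return 1.0
    return 2.0 * int(np.count_nonzero(pred & truth)) / denom


def jaccard_from_dice(dsc: float) -> float:
    """Jaccard index from the Dice score: JI = DSC / (2 - DSC)."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError("Dice score must lie in [0, 1]")
    return dsc / (2.0 - dsc)


def sensitivity(counts: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN); NaN if the truth has no foreground."""
    denom = counts.tp + counts.fn
    if denom == 0:
        logger.info("no positive pixels in truth: sensitivity undefined")
        return float("nan")
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """True-negative rate TN / (TN + FP); NaN if the truth has no background."""
    denom = counts.tn + counts.fp
    if denom == 0:
        logger.info("no negative pixels in truth: specificity undefined")
        return float("nan")
    return counts.tn / denom


def two_sample_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Welch's two-sample t-test on two lists of per-image scores.

    Returns (t statistic, two-sided p-value).  Two identical zero-variance
    samples are indistinguishable and score p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("scores must be finite")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        logger.info("identical zero-variance samples: p = 1 by convention")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def evaluate_mask(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """All four metrics for one prediction."""
    counts = confusion(pred, truth)
    dsc = dice(pred, truth)
    return {
        "dice": dsc,
        "jaccard": jaccard_from_dice(dsc),
        "sensitivity": sensitivity(counts),
        "specificity": specificity(counts),
    }


def evaluation_report(
    per_image: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a per-image metric table and test methods pairwise.

    Parameters
    ----------
    per_image : DataFrame with columns image_id, method, dice, jaccard,
        sensitivity, specificity (one row per image per method).

    Returns
    -------
    aggregate : mean of each metric per method.
    ttests : Welch t statistic, p-value and significance flag for every
        unordered method pair, on the per-image Dice scores.
    """
    metrics = ["dice", "jaccard", "sensitivity", "specificity"]
    aggregate = per_image.groupby("method")[metrics].mean().reset_index()
    methods = list(aggregate["method"])
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            da = per_image.loc[per_image["method"] == ma, "dice"].to_numpy()
            db = per_image.loc[per_image["method"] == mb, "dice"].to_numpy()
            t, p = two_sample_ttest(da, db)
            rows.append({
                "method_a": ma, "method_b": mb,
                "t": t, "p": p, "significant": p <= alpha,
            })
    return aggregate, pd.DataFrame(rows)
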