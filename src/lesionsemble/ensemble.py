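"""Winner-takes-all selection among candidate segmentations.

Every candidate binary mask is reduced to its largest connected component C
and scored with

    objective = Area(C) / (A * B)  -  dist(centroid(C), centre) / halfdiag  -  penalty

where A x B is the image size, halfdiag is half the image diagonal (so both
terms live in [0, 1]), and the penalty is infinite for an entirely black or
entirely white mask — encoding the prior that a lesion is a single sizeable
blob near the image centre and that degenerate segmentations are worthless.
The candidate with the maximum objective wins outright; no mask fusion is
performed.  The winning mask is then cleaned up morphologically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

logger = logging.getLogger(__name__)

#: Fixed tie-break priority among methods (first wins ties).
METHOD_PRIORITY = ("otsu", "acm", "kapur", "hho", "gray")


@dataclass
class ComponentSummary:
    """Largest connected foreground component of a candidate mask."""

    mask: np.ndarray          # binary mask of the component only
    area_px: int
    centroid: tuple[float, float]
    norm_area: float          # area / (A*B)
    norm_distance: float      # centroid-to-centre distance / half diagonal
    empty: bool = False


@dataclass
class ObjectiveScore:
    value: float              # area_term - distance_term - penalty (-inf if penalized)
    area_term: float
    distance_term: float
    penalty: float


@dataclass
class EnsembleDecision:
    winner: str
    winning_mask_raw: np.ndarray
    winning_mask_post: np.ndarray
    scores: dict[str, ObjectiveScore] = field(default_factory=dict)
    summaries: dict[str, ComponentSummary] = field(default_factory=dict)
    fallback: bool = False


def largest_component(mask: np.ndarray) -> ComponentSummary:
    """Extract the largest 8-connected foreground component.

    Ties between equally sized components break to the first label in raster
    order.  An empty mask yields area 0 and the maximal normalized distance 1.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    centre = ((h - 1) / 2.0, (w - 1) / 2.0)
    halfdiag = np.hypot(h - 1, w - 1) / 2.0
    if not mask.any():
        return ComponentSummary(
            mask=np.zeros_like(mask, dtype=np.uint8), area_px=0,
            centroid=centre, norm_area=0.0, norm_distance=1.0, empty=True,
        )
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    lab = int(np.argmax(sizes))
    comp = labels == lab
    coords = np.argwhere(comp)
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    area = int(sizes[lab])
    dist = float(np.hypot(centroid[0] - centre[0], centroid[1] - centre[1]))
    return ComponentSummary(
        mask=comp.astype(np.uint8), area_px=area, centroid=centroid,
        norm_area=area / (h * w), norm_distance=min(dist / halfdiag, 1.0),
    )


def penalty(mask: np.ndarray) -> float:
    """Infinite penalty for an entirely black or entirely white mask, else 0."""
    mask = np.asarray(mask).astype(bool)
    s = int(mask.sum())
    return np.inf if s == 0 or s == mask.size else 0.0


def objective_score(summary: ComponentSummary, pen: float) -> ObjectiveScore:
    """Compose the objective value; an infinite penalty excludes the method."""
    if np.isinf(pen):
        return ObjectiveScore(
            value=-np.inf, area_term=summary.norm_area,
            distance_term=summary.norm_distance, penalty=pen,
        )
    return ObjectiveScore(
        value=summary.norm_area - summary.norm_distance - pen,
        area_term=summary.norm_area, distance_term=summary.norm_distance,
        penalty=pen,
    )


def select_best(
    candidates: list[tuple[str, np.ndarray]],
    erode_radius: int = 1,
    close_radius: int = 2,
) -> EnsembleDecision:
    """Score all candidate masks and keep the single best one.

    Each candidate is mapped through largest-component extraction, the
    degeneracy penalty and the objective; the arg-max wins, with ties broken
    by the fixed priority order of ``METHOD_PRIORITY``.  If every candidate
    is degenerate (all scores -inf), the raw Otsu mask is returned unscored
    as a fallback.  The winner's largest component is then post-processed.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scores: dict[str, ObjectiveScore] = {}
    summaries: dict[str, ComponentSummary] = {}
    masks = dict(candidates)
    for method, mask in candidates:
        summary = largest_component(mask)
        summaries[method] = summary
        scores[method] = objective_score(summary, penalty(mask))

    def rank(method: str) -> tuple[float, int]:
        prio = METHOD_PRIORITY.index(method) if method in METHOD_PRIORITY else len(METHOD_PRIORITY)
        return (scores[method].value, -prio)

    winner = max(scores, key=rank)
    if np.isneginf(scores[winner].value):
        logger.warning("all candidates degenerate; falling back to raw Otsu mask")
        fallback_name = "otsu" if "otsu" in masks else candidates[0][0]
        raw = np.asarray(masks[fallback_name]).astype(np.uint8)
        return EnsembleDecision(
            winner=fallback_name, winning_mask_raw=raw,
            winning_mask_post=postprocess(raw, erode_radius, close_radius),
            scores=scores, summaries=summaries, fallback=True,
        )
    raw = summaries[winner].mask
    return EnsembleDecision(
        winner=winner, winning_mask_raw=raw,
        winning_mask_post=postprocess(raw, erode_radius, close_radius),
        scores=scores, summaries=summaries,
    )


def postprocess(mask: np.ndarray, erode_radius: int = 1, close_radius: int = 2) -> np.ndarray:
    """Morphological cleanup of the winning mask.

    Erosion with a disc shrinks the region and detaches thin spurs such as
    hair strokes; closing (dilation then erosion) fills small holes and
    openings; finally only the largest component is kept.  If the cleanup
    empties the mask the input is returned unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    out = mask.astype(np.uint8)
    if erode_radius > 0:
        out = morphology.erosion(out, morphology.disk(erode_radius))
    if close_radius > 0:
        out = morphology.closing(out, morphology.disk(close_radius))
    if not out.any():
        logger.warning("postprocessing emptied the mask; returning input")
        return mask.astype(np.uint8)
    return largest_component(out).mask
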