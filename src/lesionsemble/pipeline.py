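"""End-to-end segmentation: preprocess, run all five segmenters, select.

``segment_image`` is the one-call interface the CLI, the tests and the
evaluation harness all use.  Given the same image, config and seed it is
bit-reproducible: the only stochastic stage is the Harris-hawks threshold
search, which is driven entirely by the supplied seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import active_contour, ensemble, preprocessing, thresholders
from .config import DEFAULT_CONFIG, PipelineConfig

METHODS = ("otsu", "kapur", "gray", "hho", "acm")


@dataclass
class SegmentationResult:
    """Everything one pipeline run produced."""

    preprocessed: np.ndarray
    thresholds: dict[str, int]                 # per threshold-based method
    candidate_masks: dict[str, np.ndarray]     # raw candidate masks
    decision: ensemble.EnsembleDecision
    seed: int = 0

    @property
    def mask(self) -> np.ndarray:
        """The final postprocessed lesion mask."""
        return self.decision.winning_mask_post

    @property
    def winner(self) -> str:
        return self.decision.winner

    def scores_dict(self) -> dict:
        """JSON-serializable summary (winner + all objective scores)."""
        def num(x: float) -> float | str:
            return x if np.isfinite(x) else ("-inf" if x < 0 else "inf")
        return {
            "winner": self.decision.winner,
            "fallback": self.decision.fallback,
            "seed": self.seed,
            "thresholds": self.thresholds,
            "scores": {
                m: {
                    "value": num(s.value),
                    "area_term": s.area_term,
                    "distance_term": s.distance_term,
                    "penalty": num(s.penalty),
                }
                for m, s in self.decision.scores.items()
            },
        }


def run_candidates(
    img: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
) -> tuple[dict[str, int], dict[str, np.ndarray]]:
    """Run the requested segmenters on a preprocessed image.

    Returns the per-method thresholds (where applicable) and candidate masks.
    """
    pol = config.lesion_polarity
    counts, _ = thresholders.histogram(img)
    thresholds: dict[str, int] = {}
    masks: dict[str, np.ndarray] = {}
    for method in methods:
        if method == "otsu":
            thresholds[method] = thresholders.otsu_threshold(counts)
        elif method == "kapur":
            thresholds[method] = thresholders.kapur_threshold(counts)
        elif method == "gray":
            thresholds[method] = thresholders.gray_feature_threshold(
                img, config.gray_plateau_rtol, pol
            )
        elif method == "hho":
            thresholds[method] = thresholders.hho_threshold(
                img, pop=config.hho_pop, iters=config.hho_iters, seed=seed,
                levy_beta=config.hho_levy_beta, lesion_polarity=pol,
            )
        elif method == "acm":
            masks[method] = active_contour.chan_vese_segment(
                img, mu=config.cv_mu, iters=config.cv_iters,
                tol=config.cv_tol, dt=config.cv_dt, lesion_polarity=pol,
            )
            continue
        else:
            raise ValueError(f"unknown method {method!r}")
        masks[method] = thresholders.apply_threshold(img, thresholds[method], pol)
    return thresholds, masks


def segment_image(
    raw: np.ndarray,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
) -> SegmentationResult:
    """Full pipeline on a raw (possibly RGB) image.

    Preprocesses, runs the requested candidate segmenters, scores each with
    the area/centre-distance objective and returns the winner's postprocessed
    mask along with all intermediate products.
    """
    pre = preprocessing.preprocess(raw, config)
    thresholds, masks = run_candidates(pre, config, seed, methods)
    decision = ensemble.select_best(
        [(m, masks[m]) for m in methods],
        erode_radius=config.erode_radius, close_radius=config.close_radius,
    )
    return SegmentationResult(
        preprocessed=pre, thresholds=thresholds,
        candidate_masks=masks, decision=decision, seed=seed,
    )


def segment_single_method(
    raw: np.ndarray,
    method: str,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> np.ndarray:
    """One segmenter end to end, with the same largest-component extraction
    and postprocessing the ensemble applies — for ablation comparisons."""
    pre = preprocessing.preprocess(raw, config)
    _, masks = run_candidates(pre, config, seed, (method,))
    comp = ensemble.largest_component(masks[method])
    return ensemble.postprocess(
        comp.mask, config.erode_radius, config.close_radius
    )
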