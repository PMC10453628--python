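"""Pipeline configuration.

All tunable parameters of the segmentation pipeline live in one dataclass so
that a run is fully described by (input image, config, seed).  Values can be
overridden from a YAML mapping with the same field names.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Every knob of the segmentation pipeline, with defaults.

    Attributes
    ----------
    target_size : (height, width) every image is resized to before
        segmentation.  Small working size keeps all five segmenters cheap.
    median_window : odd side length of the median-filter neighbourhood.
    contrast_low_frac, contrast_high_frac : fraction of pixels saturated at
        the bottom / top of the intensity range during contrast stretching.
    lesion_polarity : ``"dark"`` if lesions are darker than surrounding skin
        (the usual situation in dermoscopy), ``"bright"`` otherwise.
    hho_pop, hho_iters : population size and iteration budget of the
        Harris-hawks threshold search.
    hho_levy_beta : stability index of the Levy-flight step distribution.
    cv_mu : contour-length regularization weight of the Chan-Vese model
        (image intensities are scaled to [0, 1] for the evolution).
    cv_iters, cv_tol, cv_dt : iteration cap, level-set change tolerance and
        time step of the contour evolution.  Carrying the initial circle onto
        an off-centre lesion boundary at the 56 x 56 working size can need
        several thousand steps at dt = 2; evolution stops early once the
        binary segmentation is stable.
    gray_plateau_rtol : relative variation below which consecutive feature
        values count as one plateau in grey feature-histogram thresholding.
    erode_radius, close_radius : disc radii of the post-processing erosion
        and closing, in pixels at the working resolution.
    """

    target_size: tuple[int, int] = (56, 56)
    median_window: int = 3
    contrast_low_frac: float = 0.01
    contrast_high_frac: float = 0.01
    lesion_polarity: str = "dark"
    hho_pop: int = 20
    hho_iters: int = 50
    hho_levy_beta: float = 1.5
    cv_mu: float = 0.2
    cv_iters: int = 12000
    cv_tol: float = 1e-3
    cv_dt: float = 2.0
    gray_plateau_rtol: float = 0.05
    erode_radius: int = 1
    close_radius: int = 2

    def __post_init__(self) -> None:
        h, w = self.target_size
        if h < 1 or w < 1:
            raise ValueError("target_size must be positive")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be an odd positive integer")
        if not 0 <= self.contrast_low_frac + self.contrast_high_frac < 1:
            raise ValueError("contrast saturation fractions must sum to < 1")
        if self.lesion_polarity not in ("dark", "bright"):
            raise ValueError("lesion_polarity must be 'dark' or 'bright'")
        if self.hho_pop < 2 or self.hho_iters < 1:
            raise ValueError("HHO needs pop >= 2 and iters >= 1")
        if self.cv_mu < 0:
            raise ValueError("cv_mu must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML file; missing keys keep their defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "target_size" in data:
            data["target_size"] = tuple(data["target_size"])
        return cls(**data)


DEFAULT_CONFIG = PipelineConfig()
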