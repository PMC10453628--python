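"""Standardize raw dermoscopic images for segmentation.

Every segmenter downstream consumes the same representation: a 2-D float
array of grayscale intensities in [0, 255].  The preprocessing chain is
grayscale conversion -> resize to a small working grid -> median filtering
(hair and acquisition noise) -> percentile contrast stretching.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .config import DEFAULT_CONFIG, PipelineConfig

logger = logging.getLogger(__name__)

# Rec. 601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to single-channel luminance.

    Parameters
    ----------
    img : 2-D grayscale array or (H, W, 3) RGB array with values in [0, 255].

    Returns
    -------
    2-D float64 array of the same height/width.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img.copy()
    if img.ndim == 3 and img.shape[2] == 1:
        return img[:, :, 0].copy()
    if img.ndim == 3 and img.shape[2] == 3:
        return img @ _LUMA
    raise ValueError(f"unsupported channel layout: shape {img.shape}")


def resize(img: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Bilinear resize of a grayscale grid to exactly (target_h, target_w)."""
    if target_h < 1 or target_w < 1:
        raise ValueError("target dimensions must be >= 1")
    img = np.asarray(img, dtype=float)
    if img.shape == (target_h, target_w):
        return img.copy()
    out = _sk_resize(
        img, (target_h, target_w), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0.0, 255.0)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with reflective border padding.

    Replaces each pixel by the median of its ``window``x``window``
    neighbourhood.  Median filtering suppresses impulse noise and thin hair
    strokes while leaving step edges between large regions intact.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    img = np.asarray(img, dtype=float)
    return ndimage.median_filter(img, size=window, mode="reflect")


def adjust_contrast(
    img: np.ndarray, low_frac: float = 0.01, high_frac: float = 0.01
) -> np.ndarray:
    """Linear contrast stretch saturating the intensity tails.

    Maps the ``low_frac`` quantile to 0 and the ``1 - high_frac`` quantile to
    255, clipping values beyond them — the behaviour of classic intensity
    adjustment with 1% tail saturation.  A constant image has no dynamic
    range to stretch and is returned unchanged.
    """
    if not 0 <= low_frac + high_frac < 1:
        raise ValueError("low_frac + high_frac must lie in [0, 1)")
    img = np.asarray(img, dtype=float)
    lo = np.quantile(img, low_frac)
    hi = np.quantile(img, 1.0 - high_frac)
    if hi <= lo:
        logger.warning("zero dynamic range, contrast adjustment skipped")
        return img.copy()
    out = (img - lo) * (255.0 / (hi - lo))
    return np.clip(out, 0.0, 255.0)


def preprocess(img: np.ndarray, config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Full chain: grayscale, resize, median filter, contrast stretch."""
    gray = to_grayscale(img)
    h, w = config.target_size
    small = resize(gray, h, w)
    smooth = median_filter(small, config.median_window)
    return adjust_contrast(smooth, config.contrast_low_frac, config.contrast_high_frac)
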