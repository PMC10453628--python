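"""Histogram and optimization based threshold selectors.

Four of the five candidate segmenters live here:

* Otsu — minimize the weighted within-class intensity variance.
* Kapur — maximize the sum of Shannon entropies of the two classes.
* Grey feature-histogram — pick the threshold at the most stable plateau of a
  per-threshold object feature (mean connected-component area).
* Harris-hawks — a population metaheuristic minimizing the cross-entropy
  (information) distance between the image and its two-level reconstruction.

Each selector returns a single integer threshold in [0, 255]; binarisation is
``apply_threshold`` with the configured lesion polarity (lesions are darker
than surrounding skin, so "dark" means foreground = pixels <= threshold).
All entropies and divergences use the natural logarithm.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)

N_LEVELS = 256


def histogram(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin intensity histogram of an image with values in [0, 255].

    Returns
    -------
    counts : int array of length 256; ``counts[v]`` is the number of pixels
        whose rounded intensity equals ``v``.
    probabilities : counts normalized by the pixel count (sums to 1).
    """
    img = np.asarray(img, dtype=float)
    levels = np.clip(np.rint(img).astype(np.int64), 0, N_LEVELS - 1)
    counts = np.bincount(levels.ravel(), minlength=N_LEVELS)
    return counts, counts / levels.size


def apply_threshold(
    img: np.ndarray, th: int, lesion_polarity: str = "dark"
) -> np.ndarray:
    """Binarise an image at threshold ``th``.

    With "dark" polarity the foreground is ``pixel <= th``; with "bright" it
    is ``pixel > th``.
    """
    if not 0 <= th <= N_LEVELS - 1:
        raise ValueError("threshold must lie in [0, 255]")
    img = np.asarray(img, dtype=float)
    if lesion_polarity == "dark":
        return (img <= th).astype(np.uint8)
    if lesion_polarity == "bright":
        return (img > th).astype(np.uint8)
    raise ValueError("lesion_polarity must be 'dark' or 'bright'")


def _valid_thresholds(counts: np.ndarray) -> np.ndarray:
    """Thresholds th for which both classes {<= th} and {> th} are nonempty."""
    cum = np.cumsum(counts)
    total = cum[-1]
    return np.nonzero((cum > 0) & (cum < total))[0]


def _degenerate_level(counts: np.ndarray) -> int:
    return int(np.nonzero(counts)[0][0])


def otsu_threshold(counts: np.ndarray) -> int:
    """Otsu's threshold: arg-min of the weighted within-class variance.

    sigma_w^2(th) = w1(th) sigma_1^2(th) + w2(th) sigma_2^2(th), where class 1
    holds intensities <= th and class 2 the rest.  Only thresholds leaving
    both classes nonempty are candidates; ties break to the smallest th.
    """
    counts = np.asarray(counts, dtype=float)
    valid = _valid_thresholds(counts)
    if valid.size == 0:
        logger.warning("degenerate histogram: single grey level")
        return _degenerate_level(counts)
    levels = np.arange(N_LEVELS, dtype=float)
    p = counts / counts.sum()
    w1 = np.cumsum(p)
    m1 = np.cumsum(p * levels)
    s1 = np.cumsum(p * levels**2)
    total_m, total_s = m1[-1], s1[-1]
    w2 = 1.0 - w1
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = m1 / w1
        mu2 = (total_m - m1) / w2
        var1 = s1 / w1 - mu1**2
        var2 = (total_s - s1) / w2 - mu2**2
    sigma_w = w1 * var1 + w2 * var2
    vals = sigma_w[valid]
    # ties (within floating-point noise of the minimum) break to smallest th
    m = vals.min()
    tol = 1e-9 * max(1.0, abs(m))
    return int(valid[np.nonzero(vals <= m + tol)[0][0]])


def _class_entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of the conditional distribution of one class."""
    mass = p.sum()
    if mass <= 0:
        return 0.0
    q = p[p > 0] / mass
    return float(-np.sum(q * np.log(q)))


def kapur_threshold(counts: np.ndarray) -> int:
    """Kapur's maximum-entropy threshold.

    Maximizes H_background(th) + H_foreground(th), the Shannon entropies of
    the intensity distributions conditioned on each class.  Empty histogram
    bins contribute nothing; only thresholds with two nonempty classes are
    candidates; ties break to the smallest th.
    """
    counts = np.asarray(counts, dtype=float)
    valid = _valid_thresholds(counts)
    if valid.size == 0:
        logger.warning("degenerate histogram: single grey level")
        return _degenerate_level(counts)
    p = counts / counts.sum()
    vals = np.array([
        _class_entropy(p[: th + 1]) + _class_entropy(p[th + 1 :]) for th in valid
    ])
    # ties (within floating-point noise of the maximum) break to smallest th
    m = vals.max()
    tol = 1e-9 * max(1.0, abs(m))
    return int(valid[np.nonzero(vals >= m - tol)[0][0]])


def _mean_component_area(mask: np.ndarray) -> float:
    """Mean area of 8-connected foreground components.

    Degenerate masks (empty, or covering the whole frame so that there is no
    object distinct from the background) carry no object feature and score 0.
    """
    if not mask.any() or mask.all():
        return 0.0
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    return float(np.count_nonzero(labels) / n)


def gray_feature_threshold(
    img: np.ndarray, plateau_rtol: float = 0.05, lesion_polarity: str = "dark"
) -> int:
    """Grey feature-histogram threshold.

    For every candidate threshold the image is binarised and a feature of the
    resulting objects — the mean connected-component area — is measured,
    giving a feature histogram over thresholds.  Objects that are stable over
    a long range of thresholds correspond to real image structure, so the
    midpoint of the longest run of thresholds whose feature varies by less
    than ``plateau_rtol`` (relative) is returned.  If no plateau longer than
    one threshold exists the method falls back to Otsu.
    """
    img = np.asarray(img, dtype=float)
    feat = np.empty(N_LEVELS)
    for th in range(N_LEVELS):
        feat[th] = _mean_component_area(apply_threshold(img, th, lesion_polarity))

    best_start, best_len = 0, 1
    start = 0
    for th in range(1, N_LEVELS):
        prev = feat[th - 1]
        stable = prev > 0 and abs(feat[th] - prev) <= plateau_rtol * prev
        if not stable:
            start = th
        if th - start + 1 > best_len:
            best_start, best_len = start, th - start + 1

    if best_len <= 1:
        logger.warning("no stable feature plateau; falling back to Otsu")
        counts, _ = histogram(img)
        return otsu_threshold(counts)
    return int(best_start + (best_len - 1) // 2)


def cross_entropy_distance(img: np.ndarray, mask: np.ndarray) -> float:
    """Information distance between an image and its two-level reconstruction.

    The reconstruction S replaces every pixel by the mean intensity of its
    class (foreground / background under ``mask``); the distance is the
    pixelwise generalized Kullback–Leibler divergence

        Dist(I, S) = sum_j I_j ln(I_j / S_j)

    the classic minimum-cross-entropy thresholding criterion.  Because each
    class mean preserves its class's intensity sum, the distance is
    non-negative and zero exactly when the reconstruction reproduces the
    image.  Pixels with I_j = 0 contribute 0; a zero class mean is smoothed
    with eps = 1e-12.  A segmentation with an empty class is degenerate and
    scores +inf.
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    n_fg = int(mask.sum())
    if n_fg == 0 or n_fg == mask.size:
        return np.inf
    mu_fg = float(img[mask].mean())
    mu_bg = float(img[~mask].mean())
    recon = np.where(mask, mu_fg, mu_bg)
    nz = img > 0
    return float(np.sum(img[nz] * np.log(img[nz] / np.maximum(recon[nz], 1e-12))))


def _threshold_fitness(img: np.ndarray, th: int, lesion_polarity: str) -> float:
    return cross_entropy_distance(img, apply_threshold(img, th, lesion_polarity))


def _levy_step(rng: np.random.Generator, beta: float) -> float:
    """Levy-flight step (Mantegna's algorithm)."""
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma)
    v = rng.normal(0.0, 1.0)
    return 0.01 * u / abs(v) ** (1 / beta)


def hho_threshold(
    img: np.ndarray,
    pop: int = 20,
    iters: int = 50,
    seed: int = 0,
    levy_beta: float = 1.5,
    lesion_polarity: str = "dark",
) -> int:
    """Harris-hawks optimized threshold.

    Runs the standard Harris-hawks optimizer over the scalar threshold domain
    [0, 255], minimizing the cross-entropy distance of the resulting binary
    segmentation.  Hawks explore while the prey's escape energy |E| >= 1 and
    switch between soft/hard besiege moves (optionally with Levy-flight rapid
    dives) as the energy decays over iterations.  Positions are clamped to
    [0, 255] and rounded to the nearest integer level for evaluation; the
    initial population is spread over the image's own intensity range, since
    every threshold outside it yields a degenerate (infinite-distance)
    segmentation.  The run is fully reproducible from ``seed``.
    """
    if pop < 2 or iters < 1:
        raise ValueError("need pop >= 2 and iters >= 1")
    img = np.asarray(img, dtype=float)
    rng = np.random.default_rng(seed)
    lb, ub = 0.0, float(N_LEVELS - 1)

    cache: dict[int, float] = {}

    def fitness(x: float) -> float:
        th = int(round(min(max(x, lb), ub)))
        if th not in cache:
            cache[th] = _threshold_fitness(img, th, lesion_polarity)
        return cache[th]

    init_lo = float(img.min())
    init_hi = max(float(img.max()) - 1.0, init_lo)
    X = rng.uniform(init_lo, init_hi, size=pop)
    fit = np.array([fitness(x) for x in X])
    best_i = int(np.argmin(fit))
    rabbit_x, rabbit_f = X[best_i], fit[best_i]

    for t in range(iters):
        mean_x = X.mean()
        for i in range(pop):
            E0 = rng.uniform(-1.0, 1.0)
            E = 2.0 * E0 * (1.0 - (t + 1) / iters)
            J = 2.0 * (1.0 - rng.random())
            if abs(E) >= 1.0:  # exploration
                if rng.random() >= 0.5:
                    xr = X[rng.integers(pop)]
                    new = xr - rng.random() * abs(xr - 2.0 * rng.random() * X[i])
                else:
                    new = (rabbit_x - mean_x) - rng.random() * (
                        lb + rng.random() * (ub - lb)
                    )
            else:  # exploitation
                r = rng.random()
                if r >= 0.5 and abs(E) >= 0.5:  # soft besiege
                    new = (rabbit_x - X[i]) - E * abs(J * rabbit_x - X[i])
                elif r >= 0.5:  # hard besiege
                    new = rabbit_x - E * abs(rabbit_x - X[i])
                else:  # besiege with progressive rapid dives
                    anchor = X[i] if abs(E) >= 0.5 else mean_x
                    Y = rabbit_x - E * abs(J * rabbit_x - anchor)
                    if fitness(Y) < fit[i]:
                        new = Y
                    else:
                        Z = Y + rng.random() * _levy_step(rng, levy_beta)
                        new = Z if fitness(Z) < fit[i] else X[i]
            new = min(max(new, lb), ub)
            new_f = fitness(new)
            if new_f <= fit[i]:
                X[i], fit[i] = new, new_f
            if new_f < rabbit_f:
                rabbit_x, rabbit_f = new, new_f

    return int(round(rabbit_x))
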