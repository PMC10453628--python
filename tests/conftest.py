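"""Shared fixtures.

The heavyweight fixture here is a single full run of the pipeline over the
default 50-image synthetic suite; several acceptance-level checks (energy
descent, ensemble superiority, reproducibility) share it so the suite is
segmented exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lesionsemble import pipeline, synthetic
from lesionsemble.config import PipelineConfig
from lesionsemble.ensemble import largest_component, postprocess
from lesionsemble.evaluation import dice

SUITE_SEED = 0
SUITE_N = 50


@pytest.fixture(scope="session")
def clean_disc():
    """One artefact-free dark-lesion fixture at working resolution."""
    spec = synthetic.FixtureSpec(seed=11, supersample=1, noise_sd=0.0,
                                 lesion_sd=0.0, skin_sd=0.0)
    img, mask = synthetic.generate(spec)
    return img, mask


@pytest.fixture(scope="session")
def suite():
    return synthetic.generate_suite(n=SUITE_N, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def suite_results(suite):
    """Pipeline output plus per-method Dice for every suite fixture.

    Individual methods are given the same largest-component extraction and
    morphological cleanup as the ensemble winner, so the comparison isolates
    the value of the selection step itself.
    """
    cfg = PipelineConfig()
    records = []
    results = []
    for i, fx in enumerate(suite):
        res = pipeline.segment_image(fx.image, cfg, seed=SUITE_SEED * 1000 + i)
        results.append(res)
        row = {"stratum": fx.stratum, "winner": res.winner,
               "ensemble": dice(res.mask, fx.mask)}
        for m in pipeline.METHODS:
            cleaned = postprocess(largest_component(res.candidate_masks[m]).mask,
                                  cfg.erode_radius, cfg.close_radius)
            row[m] = dice(cleaned, fx.mask)
        records.append(row)
    return results, pd.DataFrame(records)


def brute_force_otsu(pixels: np.ndarray) -> int:
    """Independent exhaustive Otsu: per-threshold class stats from raw pixels."""
    levels = np.clip(np.rint(np.asarray(pixels, float)).astype(int), 0, 255).ravel()
    vals, ths = [], []
    for th in range(256):
        lo, hi = levels[levels <= th], levels[levels > th]
        if lo.size == 0 or hi.size == 0:
            continue
        w1, w2 = lo.size / levels.size, hi.size / levels.size
        vals.append(w1 * lo.var() + w2 * hi.var())
        ths.append(th)
    if not ths:
        return int(levels[0])
    vals = np.asarray(vals)
    m = vals.min()
    tol = 1e-9 * max(1.0, abs(m))  # smallest th within fp noise of the optimum
    return ths[int(np.nonzero(vals <= m + tol)[0][0])]


def brute_force_kapur(pixels: np.ndarray) -> int:
    """Independent exhaustive Kapur: entropies computed from raw pixels."""
    levels = np.clip(np.rint(np.asarray(pixels, float)).astype(int), 0, 255).ravel()
    n = levels.size

    def entropy(sub: np.ndarray) -> float:
        if sub.size == 0:
            return 0.0
        _, counts = np.unique(sub, return_counts=True)
        q = counts / sub.size
        return float(-np.sum(q * np.log(q)))

    vals, ths = [], []
    for th in range(256):
        lo, hi = levels[levels <= th], levels[levels > th]
        if lo.size == 0 or hi.size == 0:
            continue
        vals.append(entropy(lo) + entropy(hi))
        ths.append(th)
    if not ths:
        return int(levels[0])
    vals = np.asarray(vals)
    m = vals.max()
    tol = 1e-9 * max(1.0, abs(m))
    return ths[int(np.nonzero(vals >= m - tol)[0][0])]


def random_test_images(n: int, seed: int, shape=(56, 56)):
    """Random grayscale images mixing flat-noise, bimodal and low-range cases."""
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n):
        kind = i % 3
        if kind == 0:
            img = rng.integers(0, 256, size=shape).astype(float)
        elif kind == 1:
            lo = rng.normal(70, 15, size=shape)
            hi = rng.normal(180, 15, size=shape)
            pick = rng.random(shape) < rng.uniform(0.2, 0.8)
            img = np.where(pick, lo, hi)
        else:
            base = rng.integers(80, 140)
            img = base + rng.normal(0, rng.uniform(2, 12), size=shape)
        images.append(np.clip(img, 0, 255))
    return images
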