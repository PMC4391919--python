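"""Phenotype-permutation calibration of scale-space detection.

Small penalties flood the credibility maps with false positives. Two
frequentist guards are computed from random permutations of the phenotype
vector (the no-association null):

* a lower bound lambda* per inference mode -- the smallest grid value from
  which onward at least ``level`` of the permutations produce no false
  detection;
* a lambda-dependent credibility level alpha(lambda) -- the ``level``
  empirical quantile, across permutations, of the maximum marginal sign
  probability over all effects; detection then thresholds at
  max(alpha(lambda), 0.975).

A false detection counts loci whose credibility type is +/-1 or +/-0.75;
weaker members of a combined effect (+/-0.25) are not counted.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .combined import PairCatalog, effect_set, enumerate_pairs
from .data import as_genotype_array, as_phenotype_array
from .inference import (
    InferenceConfig,
    credibility_types,
    hpw_select,
    pw_detect,
    types_from_flags,
)
from .sampler import SamplerConfig, _fit
from .scalespace import ScaleSpaceMaps, child_seed

__all__ = [
    "CalibrationResult",
    "false_positive_count",
    "permutation_lambda_threshold",
    "alpha_curve",
    "calibrate_thresholds",
    "detect_with_alpha_curve",
]

ALPHA_FLOOR = 0.975


@dataclass
class CalibrationResult:
    """Permutation-calibration output for one inference mode."""

    mode: str                      # "pw", "hpw" or "alpha"
    grid: np.ndarray
    n_perm: int
    level: float
    seed: int
    lambda_threshold: float | None = None
    fp_counts: np.ndarray | None = None   # (R, n_perm) false-positive counts
    alpha: np.ndarray | None = None       # (R,) credibility curve

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"lambda": self.grid})
        if self.alpha is not None:
            df["alpha"] = self.alpha
        if self.fp_counts is not None:
            df["zero_fp_fraction"] = (self.fp_counts == 0).mean(axis=1)
        return df


def false_positive_count(types: np.ndarray) -> int:
    """Number of loci typed +/-1 or +/-0.75 (weaker members do not count)."""
    t = np.asarray(types, dtype=float)
    return int(np.sum(np.abs(t) > 0.5))


def _threshold_from_fp(grid, fp_counts, level) -> float | None:
    zero_frac = (fp_counts == 0).mean(axis=1)
    ok = zero_frac >= level
    if not ok[-1]:
        return None
    t = len(ok)
    while t > 0 and ok[t - 1]:
        t -= 1
    return float(grid[t])


def _alpha_from_maxima(maxima: np.ndarray, level: float) -> np.ndarray:
    """Conservative empirical quantile: smallest order statistic m_(i) with
    i/n >= level."""
    R, P = maxima.shape
    idx = int(np.ceil(level * P)) - 1
    return np.sort(maxima, axis=1)[:, idx]


def _default_cell(
    Xa: np.ndarray,
    catalog: PairCatalog | None,
    sampler_config: SamplerConfig,
    inference_config: InferenceConfig,
):
    """Build the per-(permutation, lambda) statistic function: fit a chain on
    the permuted phenotypes and return (fp_pw, fp_hpw, max q)."""

    def cell(y_perm: np.ndarray, lam: float, seed: int):
        cfg = replace(sampler_config, lambda_mode="fixed", lam=float(lam), seed=seed)
        draws = _fit(Xa, y_perm, cfg)
        eff = effect_set(draws, catalog)
        det_pw = pw_detect(eff, inference_config.alpha_pw)
        det_hpw = hpw_select(eff, inference_config.alpha_hpw)
        fp_pw = false_positive_count(credibility_types(det_pw))
        fp_hpw = false_positive_count(credibility_types(det_hpw))
        return fp_pw, fp_hpw, float(det_pw.q.max())

    return cell


def _null_sweep(y, grid, n_perm, seed, cell, progress=False):
    """Evaluate ``cell`` on every (lambda, permutation) combination.

    The same permutation set is reused across all lambda so per-lambda
    results share nulls; chains are seeded by (seed, permutation, row).
    """
    ya = as_phenotype_array(y)
    rng = np.random.Generator(np.random.PCG64(child_seed(seed, 0xBEEF)))
    perms = [rng.permutation(ya.size) for _ in range(n_perm)]
    R = len(grid)
    out = np.empty((R, n_perm), dtype=object)
    for p, perm in enumerate(perms):
        y_perm = ya[perm]
        for i, lam in enumerate(grid):
            out[i, p] = cell(y_perm, float(lam), child_seed(seed, p + 1, i))
        if progress:
            print(f"  permutation {p + 1}/{n_perm}")
    return out


def permutation_lambda_threshold(
    X,
    y,
    grid: np.ndarray,
    sampler_config: SamplerConfig | None = None,
    inference_config: InferenceConfig | None = None,
    n_perm: int = 100,
    level: float = 0.95,
    mode: str = "pw",
    use_combined: bool = True,
    rho: float = 0.8,
    seed: int | None = None,
    type_fn: Callable[[np.ndarray, float], np.ndarray] | None = None,
    progress: bool = False,
) -> CalibrationResult:
    """Permutation lower bound lambda* for PW or HPW detection.

    lambda* is the smallest grid value such that, for it and every larger
    grid value, at least ``level`` of the phenotype permutations produce no
    false positive; ``None`` if even the largest grid value fails.
    ``type_fn(y_permuted, lam) -> per-locus type vector`` can replace the
    full sampler+inference pipeline (used for testing the calibration
    logic in isolation).
    """
    if mode not in ("pw", "hpw"):
        raise ValueError("mode must be 'pw' or 'hpw'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = np.asarray(grid, dtype=float)
    seed = sampler_config.seed if seed is None and sampler_config else (seed or 0)
    if type_fn is not None:
        cell = lambda yp, lam, s: false_positive_count(type_fn(yp, lam))
        stats = _null_sweep(y, grid, n_perm, seed, cell, progress)
        fp = stats.astype(int)
    else:
        Xa = as_genotype_array(X)
        catalog = enumerate_pairs(Xa, rho) if use_combined else None
        inference_config = inference_config or InferenceConfig()
        cell = _default_cell(Xa, catalog, sampler_config, inference_config)
        stats = _null_sweep(y, grid, n_perm, seed, cell, progress)
        pick = 0 if mode == "pw" else 1
        fp = np.vectorize(lambda t: t[pick])(stats).astype(int)
    return CalibrationResult(
        mode=mode,
        grid=grid,
        n_perm=n_perm,
        level=level,
        seed=seed,
        lambda_threshold=_threshold_from_fp(grid, fp, level),
        fp_counts=fp,
    )


def alpha_curve(
    X,
    y,
    grid: np.ndarray,
    sampler_config: SamplerConfig | None = None,
    n_perm: int = 100,
    level: float = 0.95,
    use_combined: bool = True,
    rho: float = 0.8,
    seed: int | None = None,
    maxq_fn: Callable[[np.ndarray, float], float] | None = None,
    progress: bool = False,
) -> CalibrationResult:
    """lambda-dependent credibility level alpha(lambda).

    For each lambda, alpha is the ``level`` empirical quantile (smallest
    order statistic at or above the level) across permutations of the
    maximum marginal sign probability over all effects and combined
    effects. ``maxq_fn(y_permuted, lam) -> float`` may stand in for the
    sampler pipeline.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = np.asarray(grid, dtype=float)
    seed = sampler_config.seed if seed is None and sampler_config else (seed or 0)
    if maxq_fn is not None:
        cell = lambda yp, lam, s: float(maxq_fn(yp, lam))
        stats = _null_sweep(y, grid, n_perm, seed, cell, progress)
        maxima = stats.astype(float)
    else:
        Xa = as_genotype_array(X)
        catalog = enumerate_pairs(Xa, rho) if use_combined else None
        cell = _default_cell(Xa, catalog, sampler_config, InferenceConfig())
        stats = _null_sweep(y, grid, n_perm, seed, cell, progress)
        maxima = np.vectorize(lambda t: t[2])(stats).astype(float)
    return CalibrationResult(
        mode="alpha",
        grid=grid,
        n_perm=n_perm,
        level=level,
        seed=seed,
        alpha=_alpha_from_maxima(maxima, level),
    )


def calibrate_thresholds(
    X,
    y,
    grid: np.ndarray,
    sampler_config: SamplerConfig,
    inference_config: InferenceConfig | None = None,
    n_perm: int = 100,
    level: float = 0.95,
    use_combined: bool = True,
    rho: float = 0.8,
    seed: int | None = None,
    progress: bool = False,
) -> dict[str, CalibrationResult]:
    """All three calibrations from a single permutation sweep.

    One set of null chains yields the PW lambda threshold, the HPW lambda
    threshold and the alpha(lambda) curve simultaneously (the per-cell
    statistics differ only in post-processing).
    """
    grid = np.asarray(grid, dtype=float)
    seed = sampler_config.seed if seed is None else seed
    Xa = as_genotype_array(X)
    catalog = enumerate_pairs(Xa, rho) if use_combined else None
    inference_config = inference_config or InferenceConfig()
    cell = _default_cell(Xa, catalog, sampler_config, inference_config)
    stats = _null_sweep(y, grid, n_perm, seed, cell, progress)
    fp_pw = np.vectorize(lambda t: t[0])(stats).astype(int)
    fp_hpw = np.vectorize(lambda t: t[1])(stats).astype(int)
    maxima = np.vectorize(lambda t: t[2])(stats).astype(float)
    common = dict(grid=grid, n_perm=n_perm, level=level, seed=seed)
    return {
        "pw": CalibrationResult(
            mode="pw", fp_counts=fp_pw,
            lambda_threshold=_threshold_from_fp(grid, fp_pw, level), **common,
        ),
        "hpw": CalibrationResult(
            mode="hpw", fp_counts=fp_hpw,
            lambda_threshold=_threshold_from_fp(grid, fp_hpw, level), **common,
        ),
        "alpha": CalibrationResult(
            mode="alpha", alpha=_alpha_from_maxima(maxima, level), **common,
        ),
    }


def detect_with_alpha_curve(
    maps: ScaleSpaceMaps, alpha: np.ndarray, floor: float = ALPHA_FLOOR
) -> np.ndarray:
    """Re-threshold a scan with the lambda-dependent credibility level.

    At each grid row, effects with marginal sign probability strictly above
    max(alpha(lambda), ``floor``) are flagged and per-locus credibility
    types recomputed. Returns the (R, m) type map.
    """
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != maps.grid.size:
        raise ValueError(
            f"alpha curve has {alpha.size} values but the scan grid {maps.grid.size}"
        )
    R, m = maps.pw_types.shape
    types = np.zeros((R, m))
    for i in range(R):
        thr = max(float(alpha[i]), floor)
        credible = maps.q[i] > thr
        types[i] = types_from_flags(
            maps.n_single,
            maps.pair_j,
            maps.pair_k,
            maps.pair_is_sum,
            credible,
            maps.sign[i],
            maps.q[i],
        )
    return types
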