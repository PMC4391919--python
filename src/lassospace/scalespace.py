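"""Scale-space scans: the sampler evaluated over a grid of tuning parameters.

Instead of committing to a single penalty lambda, the model is fitted at
every value of a logarithmically spaced grid and the per-lambda posterior
summaries are stacked into maps: a quantized posterior-mean map (7
magnitude/sign categories) and PW/HPW credibility-type maps. Rows are
independent chains with seeds derived from (master seed, row index), so a
scan is reproducible and order-independent.
"""
from __future__ import annotations

from dataclasses import dataclass, replace, field
from pathlib import Path

import numpy as np
import pandas as pd

from .combined import PairCatalog, effect_set, enumerate_pairs
from .data import as_genotype_array, as_phenotype_array, GenotypeMatrix
from .inference import InferenceConfig, credibility_types, hpw_select, pw_detect
from .sampler import PosteriorDraws, SamplerConfig, _fit

__all__ = ["lambda_grid", "quantize_effects", "scan", "ScaleSpaceMaps", "child_seed"]

#: Quantization band edges as fractions of the map maximum B
_BANDS = (1 / 20, 1 / 5, 2 / 5)


def lambda_grid(lo_exp: float, hi_exp: float, n: int) -> np.ndarray:
    """``n`` logarithmically equispaced values from 10**lo_exp to 10**hi_exp."""
    if n < 2:
        raise ValueError("a lambda grid needs at least 2 values")
    if not lo_exp < hi_exp:
        raise ValueError("require lo_exp < hi_exp")
    return np.logspace(lo_exp, hi_exp, n)


def quantize_effects(mean_matrix: np.ndarray, B: float | None = None) -> np.ndarray:
    """Quantize posterior means to 7 signed categories.

    With B the maximum |beta| over the whole map, magnitudes fall into
    0 (|b| < B/20), +/-1 = small (B/20 < |b| < B/5), +/-2 = medium
    (B/5 < |b| < 2B/5) and +/-3 = large (2B/5 < |b| <= B). Values exactly
    on a band edge take the lower band. An all-zero map quantizes to all
    zeros.
    """
    mm = np.asarray(mean_matrix, dtype=float)
    if B is None:
        B = float(np.abs(mm).max()) if mm.size else 0.0
    if B <= 0:
        return np.zeros(mm.shape, dtype=int)
    a = np.abs(mm) / B
    mag = np.zeros(mm.shape, dtype=int)
    mag[a > _BANDS[0]] = 1
    mag[a > _BANDS[1]] = 2
    mag[a > _BANDS[2]] = 3
    return mag * np.sign(mm).astype(int)


def child_seed(master: int, *indices: int) -> int:
    """Derive an independent 31-bit child seed from a master seed and indices."""
    ss = np.random.SeedSequence([int(master)] + [int(i) for i in indices])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ScaleSpaceMaps:
    """Stacked per-lambda summaries of a scale-space scan.

    Rows align with ``grid``. ``q`` and ``sign`` cover all effects (singles
    then combined pairs); the type maps are per-locus.
    """

    grid: np.ndarray
    posterior_mean: np.ndarray    # (R, m)
    categories: np.ndarray        # (R, m) ints in -3..3
    pw_types: np.ndarray          # (R, m)
    hpw_types: np.ndarray         # (R, m)
    q: np.ndarray                 # (R, E)
    sign: np.ndarray              # (R, E)
    labels: list[str]
    n_single: int
    pair_j: np.ndarray
    pair_k: np.ndarray
    pair_is_sum: np.ndarray
    B: float
    seeds: np.ndarray
    marker_names: list[str]
    inference: InferenceConfig
    draws: list[PosteriorDraws] | None = None

    @property
    def n_rows(self) -> int:
        return self.grid.size

    def save(self, outdir: str | Path) -> None:
        """Write the map matrices as TSV tables (draws are not saved)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"lambda": self.grid, "seed": self.seeds}).to_csv(
            out / "grid.tsv", sep="\t", index=False
        )
        for name, mat in (
            ("posterior_mean", self.posterior_mean),
            ("categories", self.categories),
            ("pw_types", self.pw_types),
            ("hpw_types", self.hpw_types),
        ):
            pd.DataFrame(mat, columns=self.marker_names).to_csv(
                out / f"{name}.tsv", sep="\t", index=False
            )
        pd.DataFrame(self.q, columns=self.labels).to_csv(
            out / "q.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.sign, columns=self.labels).to_csv(
            out / "sign.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"j": self.pair_j, "k": self.pair_k,
             "kind": np.where(self.pair_is_sum, "sum", "difference")}
        ).to_csv(out / "pairs.tsv", sep="\t", index=False)

    @staticmethod
    def load(outdir: str | Path) -> "ScaleSpaceMaps":
        out = Path(outdir)
        gridf = pd.read_csv(out / "grid.tsv", sep="\t")
        mats = {
            name: pd.read_csv(out / f"{name}.tsv", sep="\t")
            for name in ("posterior_mean", "categories", "pw_types", "hpw_types")
        }
        qf = pd.read_csv(out / "q.tsv", sep="\t")
        sf = pd.read_csv(out / "sign.tsv", sep="\t")
        pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
        marker_names = list(mats["posterior_mean"].columns)
        pm = mats["posterior_mean"].to_numpy(float)
        return ScaleSpaceMaps(
            grid=gridf["lambda"].to_numpy(float),
            posterior_mean=pm,
            categories=mats["categories"].to_numpy(int),
            pw_types=mats["pw_types"].to_numpy(float),
            hpw_types=mats["hpw_types"].to_numpy(float),
            q=qf.to_numpy(float),
            sign=sf.to_numpy(int),
            labels=list(qf.columns),
            n_single=len(marker_names),
            pair_j=pairs["j"].to_numpy(int),
            pair_k=pairs["k"].to_numpy(int),
            pair_is_sum=(pairs["kind"] == "sum").to_numpy(),
            B=float(np.abs(pm).max()) if pm.size else 0.0,
            seeds=gridf["seed"].to_numpy(int),
            marker_names=marker_names,
            inference=InferenceConfig(),
        )


def scan(
    X,
    y,
    grid: np.ndarray,
    sampler_config: SamplerConfig,
    inference_config: InferenceConfig | None = None,
    use_combined: bool = False,
    rho: float = 0.8,
    catalog: PairCatalog | None = None,
    store_draws: bool = False,
    progress: bool = False,
) -> ScaleSpaceMaps:
    """Fit the model at every grid lambda and assemble scale-space maps.

    Each row uses an independent chain seeded by
    ``child_seed(sampler_config.seed, row index)``; results therefore do not
    depend on evaluation order. ``use_combined`` enumerates combined-effect
    pairs from X at threshold ``rho`` (or uses a pre-built ``catalog``) and
    includes them in PW/HPW detection.
    """
    inference_config = inference_config or InferenceConfig()
    grid = np.asarray(grid, dtype=float)
    Xa = as_genotype_array(X)
    ya = as_phenotype_array(y)
    names = X.marker_names if isinstance(X, GenotypeMatrix) else [
        f"m{j + 1}" for j in range(Xa.shape[1])
    ]
    m = Xa.shape[1]
    if use_combined and catalog is None:
        catalog = enumerate_pairs(Xa, rho)
    if not use_combined:
        catalog = None

    R = grid.size
    n_pairs = 0 if catalog is None else len(catalog)
    mean = np.empty((R, m))
    pw_types = np.empty((R, m))
    hpw_types = np.empty((R, m))
    qmat = np.empty((R, m + n_pairs))
    smat = np.empty((R, m + n_pairs), dtype=int)
    seeds = np.empty(R, dtype=int)
    labels: list[str] | None = None
    kept: list[PosteriorDraws] = []
    for i, lam in enumerate(grid):
        seeds[i] = child_seed(sampler_config.seed, i)
        cfg = replace(
            sampler_config, lambda_mode="fixed", lam=float(lam), seed=int(seeds[i])
        )
        try:
            draws = _fit(Xa, ya, cfg)
        except Exception as exc:
            raise RuntimeError(f"sampler failed at lambda={lam:g} (row {i})") from exc
        draws.marker_names = list(names)
        eff = effect_set(draws, catalog)
        labels = labels or list(eff.labels)
        det_pw = pw_detect(eff, inference_config.alpha_pw)
        det_hpw = hpw_select(eff, inference_config.alpha_hpw)
        mean[i] = draws.beta.mean(axis=0)
        qmat[i] = det_pw.q
        smat[i] = det_pw.sign
        pw_types[i] = credibility_types(det_pw)
        hpw_types[i] = credibility_types(det_hpw)
        if store_draws:
            kept.append(draws)
        if progress:
            print(f"  lambda {lam:10.4g} ({i + 1}/{R})")

    B = float(np.abs(mean).max()) if mean.size else 0.0
    return ScaleSpaceMaps(
        grid=grid,
        posterior_mean=mean,
        categories=quantize_effects(mean, B),
        pw_types=pw_types,
        hpw_types=hpw_types,
        q=qmat,
        sign=smat,
        labels=labels or list(names),
        n_single=m,
        pair_j=catalog.j.copy() if catalog is not None else np.empty(0, dtype=int),
        pair_k=catalog.k.copy() if catalog is not None else np.empty(0, dtype=int),
        pair_is_sum=(
            catalog.is_sum.copy() if catalog is not None else np.empty(0, dtype=bool)
        ),
        B=B,
        seeds=seeds,
        marker_names=list(names),
        inference=inference_config,
        draws=kept if store_draws else None,
    )
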