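"""Gibbs samplers for Bayesian LASSO and Bayesian ridge regression.

The regression model is

    y = mu 1 + X beta + eps,    eps ~ N(0, sigma^2 I),

with a conditional Laplace shrinkage prior on the marker effects (LASSO,
via the scale-mixture representation) or a Gaussian prior beta ~
N(0, sigma^2/lambda I) (ridge). The tuning parameter lambda is either held
fixed -- the mode used by scale-space scans -- or given the scale-invariant
prior p(lambda) ~ 1/lambda and sampled.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .data import GenotypeMatrix, Phenotypes, as_genotype_array, as_phenotype_array

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "SamplerError",
    "gibbs_blasso",
    "gibbs_bridge",
    "posterior_summary",
    "mcse",
]


class SamplerError(RuntimeError):
    """Numerical failure inside a Gibbs chain."""


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration of one Gibbs chain.

    Parameters
    ----------
    model
        ``"lasso"`` (Laplace prior) or ``"ridge"`` (Gaussian prior).
    lambda_mode
        ``"fixed"`` uses the penalty ``lam`` throughout; ``"random"`` samples
        lambda under p(lambda) ~ 1/lambda (optionally tempered by a proper
        gamma hyperprior via ``lambda_shape``/``lambda_rate``).
    burn_in, thin, n_draws
        Discard ``burn_in`` sweeps, then retain every ``thin``-th sweep until
        ``n_draws`` draws are kept. The production schedule is burn-in 25000,
        thin 4, 10000 draws for fixed lambda and burn-in 70000, thin 10,
        15000 draws for random lambda; short exploratory chains use
        :func:`SamplerConfig.test_schedule`.
    seed
        Seed of the chain's single PCG64 generator; recorded in the output.
    center_y
        If True the response is centred and mu is fixed at its sample mean
        instead of being sampled under a flat prior.
    standardize
        If True, columns of X are centred and scaled to unit standard
        deviation before fitting (off by default: -1/+1 genotype codes are
        used as-is).
    keep_tau2
        Retain the local scale draws tau_j^2 (LASSO only).
    """

    model: str = "lasso"
    lambda_mode: str = "fixed"
    lam: float | None = None
    burn_in: int = 25_000
    thin: int = 4
    n_draws: int = 10_000
    seed: int = 0
    center_y: bool = False
    standardize: bool = False
    keep_tau2: bool = False
    lambda_shape: float = 0.0
    lambda_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("lasso", "ridge"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.lambda_mode not in ("fixed", "random"):
            raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")
        if self.lambda_mode == "fixed":
            if self.lam is None or not self.lam > 0:
                raise ValueError("fixed lambda_mode requires lam > 0")
        if self.burn_in < 0 or self.thin < 1 or self.n_draws < 1:
            raise ValueError("require burn_in >= 0, thin >= 1, n_draws >= 1")
        if self.lambda_shape < 0 or self.lambda_rate < 0:
            raise ValueError("gamma hyperprior parameters must be >= 0")

    @staticmethod
    def default_random(model: str = "lasso", seed: int = 0, **kw) -> "SamplerConfig":
        """Production schedule for a random tuning parameter."""
        return SamplerConfig(
            model=model, lambda_mode="random", lam=None,
            burn_in=70_000, thin=10, n_draws=15_000, seed=seed, **kw,
        )

    @staticmethod
    def test_schedule(
        model: str = "lasso", lam: float | None = 1.0, seed: int = 0, **kw
    ) -> "SamplerConfig":
        """Short schedule (burn-in 2000, thin 2, 2000 draws) for scans/tests."""
        mode = "fixed" if lam is not None else "random"
        return SamplerConfig(
            model=model, lambda_mode=mode, lam=lam,
            burn_in=2_000, thin=2, n_draws=2_000, seed=seed, **kw,
        )


@dataclass
class PosteriorDraws:
    """Retained MCMC draws from one chain."""

    beta: np.ndarray          # (S, m)
    mu: np.ndarray            # (S,)
    sigma2: np.ndarray        # (S,)
    tau2: np.ndarray | None   # (S, m) or None
    lam: np.ndarray | None    # (S,) when lambda is random, else None
    config: SamplerConfig
    marker_names: list[str]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def m(self) -> int:
        return self.beta.shape[1]


_ERR_NAMES = {_kernels.ERR_BETA: "beta", _kernels.ERR_SIGMA2: "sigma^2"}


def _fit(X, y, config: SamplerConfig) -> PosteriorDraws:
    Xa = as_genotype_array(X)
    ya = as_phenotype_array(y)
    names = X.marker_names if isinstance(X, GenotypeMatrix) else [
        f"m{j + 1}" for j in range(Xa.shape[1])
    ]
    if Xa.shape[0] != ya.size:
        raise ValueError(
            f"genotypes have {Xa.shape[0]} rows but phenotypes {ya.size} values"
        )
    if np.isnan(Xa).any():
        raise ValueError(
            "design matrix contains missing entries; impute or zero them first"
        )
    Xa = np.asarray(Xa, dtype=np.float64)
    if config.standardize:
        mu_c = Xa.mean(axis=0)
        sd_c = Xa.std(axis=0, ddof=0)
        if np.any(sd_c == 0):
            raise ValueError("cannot standardize a constant marker column")
        Xa = (Xa - mu_c) / sd_c
    Xt = np.ascontiguousarray(Xa.T)

    sample_mu = not config.center_y
    ybar = float(ya.mean())
    y_used = ya - ybar if config.center_y else ya

    random_lam = config.lambda_mode == "random"
    lam_init = 1.0 if random_lam else float(config.lam)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    beta, mu, sig, tau, lamv, err, err_it = _kernels.run_chain(
        Xt,
        np.asarray(y_used, dtype=np.float64),
        config.model == "ridge",
        lam_init,
        random_lam,
        sample_mu,
        config.burn_in,
        config.thin,
        config.n_draws,
        config.lambda_shape,
        config.lambda_rate,
        config.keep_tau2 and config.model == "lasso",
        rng,
    )
    if err != _kernels.ERR_NONE:
        raise SamplerError(
            f"degenerate draw for {_ERR_NAMES[err]} at iteration {err_it}"
            f" (model={config.model}, lambda_mode={config.lambda_mode})"
        )
    if config.center_y:
        mu = mu + ybar
    return PosteriorDraws(
        beta=beta,
        mu=mu,
        sigma2=sig,
        tau2=tau if tau.shape[0] else None,
        lam=lamv if random_lam else None,
        config=config,
        marker_names=list(names),
    )


def gibbs_blasso(X, y, config: SamplerConfig) -> PosteriorDraws:
    """Sample the Bayesian LASSO posterior by Gibbs sampling.

    ``X`` must be free of missing entries (apply an imputation policy
    first); draws are bit-reproducible given ``config.seed``.
    """
    if config.model != "lasso":
        config = replace(config, model="lasso")
    return _fit(X, y, config)


def gibbs_bridge(X, y, config: SamplerConfig) -> PosteriorDraws:
    """Sample the Bayesian ridge posterior (beta ~ N(0, sigma^2/lambda I))."""
    if config.model != "ridge":
        config = replace(config, model="ridge")
    return _fit(X, y, config)


def fit(X, y, config: SamplerConfig) -> PosteriorDraws:
    """Dispatch on ``config.model``."""
    return _fit(X, y, config)


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-coefficient posterior mean, sd and sign proportions.

    Draws exactly equal to zero (possible only for degenerate inputs) are
    counted toward neither sign, so ``p_pos + p_neg <= 1``.
    """
    b = draws.beta
    if b.shape[0] < 1:
        raise ValueError("no draws to summarize")
    return pd.DataFrame(
        {
            "mean": b.mean(axis=0),
            "sd": b.std(axis=0, ddof=1) if b.shape[0] > 1 else np.zeros(b.shape[1]),
            "p_pos": (b > 0).mean(axis=0),
            "p_neg": (b < 0).mean(axis=0),
        },
        index=pd.Index(draws.marker_names, name="marker"),
    )


def mcse(x: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of a chain mean by batch means.

    Splits the (possibly autocorrelated) chain into ``n_batches`` contiguous
    batches and uses the spread of batch means.
    """
    x = np.asarray(x, dtype=float).ravel()
    nb = min(n_batches, x.size)
    if nb < 2:
        return float("inf")
    size = x.size // nb
    batches = x[: nb * size].reshape(nb, size).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(nb))
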