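"""Combined effects for collinear markers.

When two genotype columns are (nearly) identical or (nearly) opposite, the
shrinkage prior distributes a single QTL effect over both coefficients and
neither is detectable on its own. Sums beta_j + beta_k (for columns that
mostly agree) and differences beta_j - beta_k (for columns that mostly
disagree) restore the detectable signal. Only pairs whose agreement or
disagreement proportion strictly exceeds a threshold rho in (0.5, 1) are
enumerated; pairs need not be physically adjacent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, as_genotype_array
from .sampler import PosteriorDraws

__all__ = ["PairCatalog", "EffectSet", "enumerate_pairs", "combined_effect_draws", "effect_set"]

DEFAULT_RHO = 0.8


@dataclass
class PairCatalog:
    """Candidate combined effects: (j, k) pairs with j < k.

    ``is_sum`` marks sum pairs (agreement proportion > rho); the rest are
    difference pairs (disagreement proportion > rho). ``proportion`` stores
    the qualifying proportion.
    """

    j: np.ndarray
    k: np.ndarray
    is_sum: np.ndarray
    proportion: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.j = np.asarray(self.j, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        self.is_sum = np.asarray(self.is_sum, dtype=bool)
        self.proportion = np.asarray(self.proportion, dtype=float)
        if not (self.j < self.k).all():
            raise ValueError("pairs must be stored with j < k")

    def __len__(self) -> int:
        return self.j.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "j": self.j,
                "k": self.k,
                "kind": np.where(self.is_sum, "sum", "difference"),
                "proportion": self.proportion,
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame, rho: float) -> "PairCatalog":
        return PairCatalog(
            df["j"].to_numpy(),
            df["k"].to_numpy(),
            (df["kind"] == "sum").to_numpy(),
            df["proportion"].to_numpy(),
            rho,
        )


def enumerate_pairs(X, rho: float = DEFAULT_RHO) -> PairCatalog:
    """Enumerate all marker pairs whose agreement/disagreement exceeds rho.

    Agreement of observation l for pair (j, k) means x_lj == x_lk with both
    entries nonzero: a neutral 0 (zeroed missing value) agrees with nothing
    and disagrees with every nonzero entry, so zero-imputed data can create
    difference pairs purely through missingness. Inclusion uses the strict
    inequality: a proportion exactly equal to rho is excluded.
    """
    if not (0.5 < rho < 1.0):
        raise ValueError(f"rho must lie in (0.5, 1), got {rho}")
    V = as_genotype_array(X)
    if np.isnan(V).any():
        raise ValueError("resolve missing entries before enumerating pairs")
    n, m = V.shape
    js, ks, sums, props = [], [], [], []
    nonzero = V != 0
    for j in range(m - 1):
        right = V[:, j + 1 :]
        eq = (V[:, [j]] == right) & nonzero[:, [j]]
        agree = eq.mean(axis=0)
        disagree = (V[:, [j]] != right).mean(axis=0)
        for off in np.nonzero(agree > rho)[0]:
            js.append(j)
            ks.append(j + 1 + off)
            sums.append(True)
            props.append(agree[off])
        for off in np.nonzero(disagree > rho)[0]:
            js.append(j)
            ks.append(j + 1 + off)
            sums.append(False)
            props.append(disagree[off])
    return PairCatalog(
        np.array(js, dtype=int),
        np.array(ks, dtype=int),
        np.array(sums, dtype=bool),
        np.array(props, dtype=float),
        rho,
    )


@dataclass
class EffectSet:
    """Posterior draws of gamma = [beta, delta]: single then combined effects.

    Column ``c < n_single`` is the single effect beta_c; column
    ``n_single + i`` is the combined effect of pair i in the catalog
    (beta_j + beta_k for sums, beta_j - beta_k for differences, j < k).
    """

    draws: np.ndarray          # (S, n_single + n_pairs)
    n_single: int
    pair_j: np.ndarray
    pair_k: np.ndarray
    pair_is_sum: np.ndarray
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pair_j = np.asarray(self.pair_j, dtype=int)
        self.pair_k = np.asarray(self.pair_k, dtype=int)
        self.pair_is_sum = np.asarray(self.pair_is_sum, dtype=bool)
        if self.draws.shape[1] != self.n_single + self.pair_j.size:
            raise ValueError("draw matrix width does not match effect count")
        if self.labels is None:
            singles = [f"b{j + 1}" for j in range(self.n_single)]
            combos = [
                f"b{j + 1}{'+' if s else '-'}b{k + 1}"
                for j, k, s in zip(self.pair_j, self.pair_k, self.pair_is_sum)
            ]
            self.labels = singles + combos

    @property
    def n_effects(self) -> int:
        return self.draws.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.pair_j.size


def combined_effect_draws(draws: PosteriorDraws, catalog: PairCatalog) -> EffectSet:
    """Append combined-effect columns to the single-effect draw matrix.

    Each combined column is the exact draw-wise linear combination of its
    parent columns.
    """
    beta = draws.beta
    m = beta.shape[1]
    if len(catalog) and (catalog.j.min() < 0 or catalog.k.max() >= m):
        raise IndexError("catalog refers to marker indices outside 0..m-1")
    cols = []
    for j, k, is_sum in zip(catalog.j, catalog.k, catalog.is_sum):
        cols.append(beta[:, j] + beta[:, k] if is_sum else beta[:, j] - beta[:, k])
    combo = np.column_stack(cols) if cols else np.empty((beta.shape[0], 0))
    singles = [f"{name}" for name in draws.marker_names]
    combos = [
        f"{draws.marker_names[j]}{'+' if s else '-'}{draws.marker_names[k]}"
        for j, k, s in zip(catalog.j, catalog.k, catalog.is_sum)
    ]
    return EffectSet(
        draws=np.hstack([beta, combo]),
        n_single=m,
        pair_j=catalog.j.copy(),
        pair_k=catalog.k.copy(),
        pair_is_sum=catalog.is_sum.copy(),
        labels=singles + combos,
    )


def effect_set(draws: PosteriorDraws, catalog: PairCatalog | None = None) -> EffectSet:
    """Build an EffectSet; without a catalog only single effects are present."""
    if catalog is None or len(catalog) == 0:
        return EffectSet(
            draws=draws.beta.copy(),
            n_single=draws.beta.shape[1],
            pair_j=np.empty(0, dtype=int),
            pair_k=np.empty(0, dtype=int),
            pair_is_sum=np.empty(0, dtype=bool),
            labels=list(draws.marker_names),
        )
    return combined_effect_draws(draws, catalog)
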