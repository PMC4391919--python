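"""Core data containers: genotype design matrices and phenotype vectors.

Genotypes from a line cross are coded -1/+1 for the two genotype classes.
A value of 0 is reserved for the "missing set to neutral" policy, and
missing entries themselves are represented by NaN until an imputation
policy resolves them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "Phenotypes", "MISSING"]

#: Sentinel used for missing genotype entries.
MISSING = np.nan

_ALLOWED = (-1.0, 0.0, 1.0)


@dataclass
class GenotypeMatrix:
    """An individuals-by-markers design matrix with entries in {-1, +1, 0, NaN}.

    Parameters
    ----------
    values
        Array of shape ``(n, m)``. NaN marks a missing genotype; 0 is the
        neutral code used when missing values are zeroed rather than imputed.
    marker_names
        Unique labels for the ``m`` columns. Autogenerated if omitted.
    individual_ids
        Labels for the ``n`` rows. Autogenerated if omitted.
    """

    values: np.ndarray
    marker_names: list[str] = field(default=None)  # type: ignore[assignment]
    individual_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D array")
        n, m = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 individuals, got {n}")
        if m < 1:
            raise ValueError("need at least 1 marker")
        finite = self.values[np.isfinite(self.values)]
        bad = ~np.isin(finite, _ALLOWED)
        if bad.any():
            raise ValueError(
                f"genotype entries must be -1, 0, +1 or missing; found {finite[bad][:5]}"
            )
        if self.marker_names is None:
            self.marker_names = [f"m{j + 1}" for j in range(m)]
        else:
            self.marker_names = [str(s) for s in self.marker_names]
        if len(self.marker_names) != m:
            raise ValueError("marker_names length does not match column count")
        if len(set(self.marker_names)) != m:
            raise ValueError("marker_names must be unique")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i + 1}" for i in range(n)]
        else:
            self.individual_ids = [str(s) for s in self.individual_ids]
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the column indices in ``keep``."""
        keep = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            self.values[:, keep],
            [self.marker_names[j] for j in keep],
            list(self.individual_ids),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(), list(self.marker_names), list(self.individual_ids)
        )


@dataclass
class Phenotypes:
    """A length-``n`` vector of trait values, row-aligned with a GenotypeMatrix."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.y.size == 0:
            raise ValueError("phenotype vector is empty")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotypes must be finite")

    @property
    def n(self) -> int:
        return self.y.size


def as_genotype_array(X) -> np.ndarray:
    """Coerce a GenotypeMatrix or array-like to a validated float array."""
    if isinstance(X, GenotypeMatrix):
        return X.values
    return GenotypeMatrix(np.asarray(X, dtype=float)).values


def as_phenotype_array(y) -> np.ndarray:
    if isinstance(y, Phenotypes):
        return y.y
    return Phenotypes(np.asarray(y, dtype=float)).y
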