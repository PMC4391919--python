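"""Readers and writers for genotype/phenotype tables, draws and manifests.

Tabular data travels as delimited text (TSV by default, CSV accepted);
posterior draws as a compressed columnar archive (.npz) with a JSON
sidecar recording the chain configuration and seed; run manifests as JSON.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MISSING, Phenotypes
from .sampler import PosteriorDraws, SamplerConfig

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "save_draws",
    "load_draws",
    "write_manifest",
]

_NA_STRINGS = {"NA", "NaN", "nan", ""}
_ALLOWED = {-1.0, 0.0, 1.0}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a delimited genotype table: header of marker names, one row per
    individual, entries -1/1/0/NA (NA becomes missing)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), na_values=list(_NA_STRINGS), keep_default_na=False
    )
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: empty genotype table")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric genotype entry ({exc})") from exc
    finite = values[np.isfinite(values)]
    bad = set(np.unique(finite)) - _ALLOWED
    if bad:
        rows, cols = np.nonzero(np.isin(values, sorted(bad)))
        raise ValueError(
            f"{path}: invalid genotype value {values[rows[0], cols[0]]:g} at "
            f"line {rows[0] + 2}, column {df.columns[cols[0]]!r}"
        )
    return GenotypeMatrix(values, list(df.columns))


def write_genotypes(X: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(X.values, columns=X.marker_names)
    df.to_csv(
        path, sep=_sep_for(path), index=False, na_rep="NA",
        float_format="%g",
    )


def read_phenotypes(path: str | Path) -> Phenotypes:
    """Read a one-column phenotype table aligned with genotype rows."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly one phenotype column")
    return Phenotypes(df.iloc[:, 0].to_numpy(dtype=float))


def write_phenotypes(y: Phenotypes, path: str | Path, name: str = "phenotype") -> None:
    path = Path(path)
    pd.DataFrame({name: y.y}).to_csv(path, sep=_sep_for(path), index=False)


def save_draws(draws: PosteriorDraws, prefix: str | Path) -> None:
    """Write draws as ``<prefix>.npz`` plus ``<prefix>.json`` (config, seed)."""
    prefix = Path(prefix)
    arrays = {"beta": draws.beta, "mu": draws.mu, "sigma2": draws.sigma2}
    if draws.tau2 is not None:
        arrays["tau2"] = draws.tau2
    if draws.lam is not None:
        arrays["lam"] = draws.lam
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": dataclasses.asdict(draws.config),
        "marker_names": draws.marker_names,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_draws(prefix: str | Path) -> PosteriorDraws:
    prefix = Path(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return PosteriorDraws(
        beta=arrays["beta"],
        mu=arrays["mu"],
        sigma2=arrays["sigma2"],
        tau2=arrays["tau2"] if "tau2" in arrays else None,
        lam=arrays["lam"] if "lam" in arrays else None,
        config=SamplerConfig(**sidecar["config"]),
        marker_names=sidecar["marker_names"],
    )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    outdir: str | Path,
    config: dict,
    master_seed: int,
    stage_seeds: dict[str, int] | None = None,
    inputs: list[str | Path] | None = None,
) -> Path:
    """Record everything needed to reproduce a run bit-identically."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "master_seed": int(master_seed),
        "stage_seeds": {k: int(v) for k, v in (stage_seeds or {}).items()},
        "config": config,
        "input_digests": {
            str(p): _digest(Path(p)) for p in (inputs or []) if Path(p).exists()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
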