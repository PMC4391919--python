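"""Rendering of scale-space maps as color images.

Loci run along the horizontal axis and log10(lambda) along the vertical.
The posterior-mean map uses a 7-color diverging palette over the signed
magnitude categories; credibility maps use a 7-color palette over the type
values {-1, -0.75, -0.25, 0, 0.25, 0.75, 1} (strong/weak members of
combined effects get intermediate colors). Horizontal lines mark
calibrated lambda thresholds; dots mark known QTL positions.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

from .scalespace import ScaleSpaceMaps

__all__ = ["render_maps", "CATEGORY_PALETTE", "TYPE_PALETTE"]

#: colors for quantized categories -L, -M, -S, 0, S, M, L
CATEGORY_PALETTE = (
    "#08306b", "#2171b5", "#9ecae1", "#f7f7f7", "#fcae91", "#de2d26", "#67000d"
)
_CATEGORY_BOUNDS = (-3.5, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, 3.5)

#: colors for credibility types -1, -0.75, -0.25, 0, 0.25, 0.75, 1
TYPE_PALETTE = (
    "#08306b", "#4292c6", "#c6dbef", "#d9d9d9", "#ffeda0", "#fd8d3c", "#bd0026"
)
_TYPE_BOUNDS = (-1.125, -0.875, -0.5, -0.125, 0.125, 0.5, 0.875, 1.125)


def _draw_panel(ax, mat, grid, cmap, norm, title):
    loglam = np.log10(grid)
    m = mat.shape[1]
    ax.pcolormesh(
        np.arange(m + 1) + 0.5, _row_edges(loglam), mat, cmap=cmap, norm=norm
    )
    ax.set_xlabel("locus")
    ax.set_ylabel(r"$\log_{10}\lambda$")
    ax.set_title(title)


def _row_edges(loglam: np.ndarray) -> np.ndarray:
    if loglam.size == 1:
        return np.array([loglam[0] - 0.5, loglam[0] + 0.5])
    mid = 0.5 * (loglam[1:] + loglam[:-1])
    first = loglam[0] - (mid[0] - loglam[0])
    last = loglam[-1] + (loglam[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


def render_maps(
    maps: ScaleSpaceMaps,
    outdir: str | Path,
    qtl_loci: list[int] | None = None,
    lambda_threshold: float | None = None,
    lambda_mean: float | None = None,
    dpi: int = 150,
) -> list[Path]:
    """Write one PNG per map plus the underlying matrices as TSV tables.

    ``qtl_loci`` (0-based analysis-frame indices) are dotted along the
    bottom; ``lambda_threshold`` (permutation limit, black) and
    ``lambda_mean`` (posterior mean of a random lambda, white) appear as
    horizontal lines.
    """
    if maps.n_rows == 0:
        raise ValueError("cannot render an empty scan")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    maps.save(out)

    cat_cmap = ListedColormap(CATEGORY_PALETTE)
    cat_norm = BoundaryNorm(_CATEGORY_BOUNDS, cat_cmap.N)
    typ_cmap = ListedColormap(TYPE_PALETTE)
    typ_norm = BoundaryNorm(_TYPE_BOUNDS, typ_cmap.N)

    panels = (
        ("posterior_mean", maps.categories, cat_cmap, cat_norm,
         "quantized posterior mean"),
        ("pw_map", maps.pw_types, typ_cmap, typ_norm, "PW credibility"),
        ("hpw_map", maps.hpw_types, typ_cmap, typ_norm, "HPW credibility"),
    )
    written = []
    ymin = np.log10(maps.grid).min()
    for name, mat, cmap, norm, title in panels:
        fig, ax = plt.subplots(figsize=(8, 4))
        _draw_panel(ax, mat, maps.grid, cmap, norm, title)
        if lambda_threshold is not None:
            ax.axhline(np.log10(lambda_threshold), color="black", lw=1.5)
        if lambda_mean is not None:
            ax.axhline(np.log10(lambda_mean), color="white", lw=1.5)
        if qtl_loci:
            ax.plot(
                np.asarray(qtl_loci) + 1,
                np.full(len(qtl_loci), ymin),
                "k.", ms=6, clip_on=False,
            )
        fig.tight_layout()
        path = out / f"{name}.png"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        written.append(path)
    return written
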