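"""Synthetic line-cross genotype/phenotype generators.

Two study designs are emulated:

* a collinear "barley-like" line cross (n=145, m=127): each individual's
  marker sequence is a two-state Markov chain over {-1, +1} with flip
  probability r per step, so adjacent markers correlate at 1-2r (~0.8 at
  the default r=0.1). Eight QTL effects are planted; some QTL markers are
  deleted before analysis so that their signal survives only in the
  flanking markers, and a small fraction of entries goes missing and is
  imputed at random.
* an uncorrelated "wheat-like" association panel (n=300, m=400):
  independent columns, a subset of loci with strong allele-frequency
  imbalance, nine planted QTL effects, no marker removal.

Phenotypes are y = X beta + eps with iid Gaussian noise of variance 8
(SD ~2.83) in both designs, computed on the COMPLETE design before any
marker removal. With the planted effect sizes this puts the heritability
Var(X beta)/Var(y) near 0.9 for the collinear design and near 0.8 for the
uncorrelated one -- the regime in which shrinkage-based QTL detection is
informative but not trivial.
The generators reproduce the statistical structure of real line-cross and
breeding-panel matrices, not any particular genotyped population; real
matrices are accepted through the standard readers instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, MISSING, Phenotypes

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "simulate_linecross_genotypes",
    "inject_missing",
    "impute_missing",
    "remove_markers",
    "make_phenotype",
    "heritability",
    "barley_fixture",
    "wheat_fixture",
]

#: Table of planted effects for the collinear design: (1-based locus, effect).
BARLEY_QTL = ((3, 3.0), (10, 3.5), (20, 4.0), (34, -2.5),
              (51, -3.0), (72, -2.0), (84, 3.0), (108, -3.0))
#: QTL markers deleted before analysis (their signal stays in flanking loci).
BARLEY_REMOVED_QTL = (3, 51, 84, 108)
#: High-missingness loci deleted before analysis. Positions are a synthetic
#: stand-in choice, placed so that the post-removal QTL indices come out at
#: 9, 19, 33, 67 and flanking pairs (2,3), (48,49), (78,79), (100,101).
BARLEY_HIGH_MISSING = (40, 60, 65, 95, 120)

#: Planted effects for the uncorrelated design: (1-based locus, effect).
WHEAT_QTL = ((7, 1.75), (76, 2.0), (118, 2.5), (162, -2.25), (181, 1.5),
             (218, -2.25), (273, -1.75), (344, 2.5), (395, -2.25))

#: Default noise level: variance 8 (SD ~2.83).
NOISE_SD = float(np.sqrt(8.0))


@dataclass
class SimulationDesign:
    """Parameters of one simulated dataset."""

    n: int
    m: int
    qtl_loci: tuple[int, ...]          # 1-based, in the complete m-marker frame
    qtl_effects: tuple[float, ...]
    noise_sd: float = NOISE_SD
    neighbor_recomb: float = 0.5       # flip probability r; corr = 1 - 2r
    missing_rate: float = 0.0
    missing_policy: str = "none"       # impute_random_pm1 | set_zero | none
    removal_set: tuple[int, ...] = ()  # 1-based loci removed before analysis
    seed: int = 0


@dataclass
class SimulatedDataset:
    """A generated dataset plus the ground truth needed to score detections."""

    X: GenotypeMatrix                  # analysis design (post removal/imputation)
    y: Phenotypes
    design: SimulationDesign
    beta_true: np.ndarray              # complete-frame effect vector (length m)
    #: per QTL (order of design.qtl_loci): 0-based column indices in the
    #: analysis design carrying that QTL's signal -- the marker itself when
    #: kept, the flanking pair when removed.
    regions: list[tuple[int, ...]] = field(default_factory=list)
    heritability: float = float("nan")
    X_complete: GenotypeMatrix | None = None


def simulate_linecross_genotypes(
    n: int, m: int, r: float, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Markov-chain line-cross genotypes over {-1, +1}.

    Within each individual (row), the first marker is uniform and each
    subsequent marker flips the previous state with probability ``r``;
    rows are independent. Adjacent columns then correlate at 1 - 2r.
    """
    if not (0.0 <= r <= 0.5):
        raise ValueError(f"flip probability r must lie in [0, 0.5], got {r}")
    if n < 1 or m < 1:
        raise ValueError("need n >= 1 and m >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.empty((n, m))
    X[:, 0] = rng.choice((-1.0, 1.0), size=n)
    if m > 1:
        flips = rng.random((n, m - 1)) < r
        steps = np.where(flips, -1.0, 1.0)
        X[:, 1:] = X[:, [0]] * np.cumprod(steps, axis=1)
    return GenotypeMatrix(X)


def inject_missing(
    X: GenotypeMatrix, rate: float, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Set each entry to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("missing rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = X.copy()
    mask = rng.random(out.values.shape) < rate
    out.values[mask] = MISSING
    return out


def impute_missing(
    X: GenotypeMatrix, policy: str, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Resolve missing entries: draw -1/+1 once at random, or zero them.

    ``impute_random_pm1`` fills each missing entry with -1 or +1 with equal
    probability, once per dataset (not per chain); ``set_zero`` uses the
    neutral code 0.
    """
    if policy not in ("impute_random_pm1", "set_zero"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    out = X.copy()
    mask = np.isnan(out.values)
    if not mask.any():
        return out
    if policy == "set_zero":
        out.values[mask] = 0.0
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out.values[mask] = rng.choice((-1.0, 1.0), size=int(mask.sum()))
    return out


def remove_markers(
    X: GenotypeMatrix, qtl_loci, removal_set
) -> tuple[GenotypeMatrix, dict[int, tuple[int, ...]]]:
    """Delete marker columns and map each QTL to its post-removal position.

    All indices are 0-based. For a QTL that survives, the map holds its new
    single index; for a removed QTL, the new indices of the nearest kept
    markers on each side (one entry if the QTL sits at an edge with no
    neighbor on one side).
    """
    m = X.m
    removal = sorted(set(int(i) for i in removal_set))
    if removal and (removal[0] < 0 or removal[-1] >= m):
        raise IndexError("removal_set outside 0..m-1")
    removed = np.zeros(m, dtype=bool)
    removed[removal] = True
    keep = np.nonzero(~removed)[0]
    new_index = -np.ones(m, dtype=int)
    new_index[keep] = np.arange(keep.size)
    flank: dict[int, tuple[int, ...]] = {}
    for q in qtl_loci:
        q = int(q)
        if not removed[q]:
            flank[q] = (int(new_index[q]),)
            continue
        left = next((i for i in range(q - 1, -1, -1) if not removed[i]), None)
        right = next((i for i in range(q + 1, m) if not removed[i]), None)
        flank[q] = tuple(int(new_index[i]) for i in (left, right) if i is not None)
    return X.subset_markers(keep), flank


def make_phenotype(
    X, beta_true, noise_sd: float, seed: int | np.random.Generator = 0
) -> Phenotypes:
    """y = X beta + eps with iid N(0, noise_sd^2) noise, drawn once."""
    V = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    beta = np.asarray(beta_true, dtype=float)
    if V.shape[1] != beta.size:
        raise ValueError("effect vector length does not match marker count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Phenotypes(V @ beta + rng.normal(0.0, noise_sd, V.shape[0]))


def heritability(X, beta_true, y) -> float:
    """Sample Var(X beta) / Var(y): the genetic fraction of trait variance."""
    V = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    ya = y.y if isinstance(y, Phenotypes) else np.asarray(y, dtype=float)
    g = V @ np.asarray(beta_true, dtype=float)
    vy = float(np.var(ya, ddof=1))
    if vy == 0:
        raise ValueError("phenotype variance is zero; heritability undefined")
    return float(np.var(g, ddof=1) / vy)


def _build_beta(m: int, qtl: tuple[tuple[int, float], ...]) -> np.ndarray:
    beta = np.zeros(m)
    for locus, eff in qtl:
        beta[locus - 1] = eff
    return beta


def barley_fixture(seed: int = 0) -> SimulatedDataset:
    """Collinear line-cross dataset with removed QTL markers.

    n=145 individuals, m=127 Markov genotypes with adjacent correlation
    ~0.8, eight planted effects, noise variance 8. Five high-missingness loci are
    deleted, ~3.4% of the remaining entries go missing and are imputed with
    random -1/+1, and four QTL markers are removed so their signal is
    carried only by the flanking markers. The phenotype is computed on the
    complete 127-marker design first.
    """
    n, m, r = 145, 127, 0.1
    design = SimulationDesign(
        n=n, m=m,
        qtl_loci=tuple(l for l, _ in BARLEY_QTL),
        qtl_effects=tuple(e for _, e in BARLEY_QTL),
        noise_sd=NOISE_SD, neighbor_recomb=r,
        missing_rate=0.034, missing_policy="impute_random_pm1",
        removal_set=tuple(sorted(BARLEY_REMOVED_QTL + BARLEY_HIGH_MISSING)),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    X0 = simulate_linecross_genotypes(n, m, r, rng)
    beta = _build_beta(m, BARLEY_QTL)
    y = make_phenotype(X0, beta, NOISE_SD, rng)

    # drop the high-missingness loci, then inject/impute missing values in
    # the remaining matrix, then remove the four QTL markers
    hm0 = [l - 1 for l in BARLEY_HIGH_MISSING]
    X1, _ = remove_markers(X0, [], hm0)
    X1 = inject_missing(X1, design.missing_rate, rng)
    X1 = impute_missing(X1, "impute_random_pm1", rng)
    # indices of the removed QTL markers within the 122-column frame
    hm_sorted = np.array(sorted(hm0))
    qtl_rm_122 = [
        (q - 1) - int((hm_sorted < q - 1).sum()) for q in BARLEY_REMOVED_QTL
    ]
    X2, _ = remove_markers(X1, [], qtl_rm_122)

    # region bookkeeping in the final frame: remove all nine loci at once
    removal_all = hm0 + [q - 1 for q in BARLEY_REMOVED_QTL]
    _, flank = remove_markers(X0, [l - 1 for l, _ in BARLEY_QTL], removal_all)
    regions = [flank[l - 1] for l, _ in BARLEY_QTL]

    return SimulatedDataset(
        X=X2, y=y, design=design, beta_true=beta, regions=regions,
        heritability=heritability(X0, beta, y), X_complete=X0,
    )


def wheat_fixture(seed: int = 0, n_imbalanced: int = 40) -> SimulatedDataset:
    """Uncorrelated association panel with allele-frequency imbalance.

    n=300 individuals, m=400 independent marker columns, nine planted
    effects, noise variance 8, no marker removal. ``n_imbalanced`` non-QTL
    columns get an allele frequency above 0.9 (or below 0.1); the QTL
    columns stay balanced except the first two, which are deliberately
    imbalanced (frequencies ~0.86 and ~0.87) and are therefore the
    hard-to-detect cases.
    """
    n, m = 300, 400
    qtl_loci = tuple(l for l, _ in WHEAT_QTL)
    design = SimulationDesign(
        n=n, m=m, qtl_loci=qtl_loci,
        qtl_effects=tuple(e for _, e in WHEAT_QTL),
        noise_sd=NOISE_SD, neighbor_recomb=0.5, seed=seed,
    )
    rng = np.random.default_rng(seed)
    p_plus = np.full(m, 0.5)
    non_qtl = np.array([j for j in range(m) if (j + 1) not in qtl_loci])
    imb = rng.choice(non_qtl, size=min(n_imbalanced, non_qtl.size), replace=False)
    p_plus[imb] = np.where(rng.random(imb.size) < 0.5, 0.95, 0.05)
    p_plus[qtl_loci[0] - 1] = 0.86   # mostly +1
    p_plus[qtl_loci[1] - 1] = 0.13   # mostly -1
    X = GenotypeMatrix(np.where(rng.random((n, m)) < p_plus, 1.0, -1.0))
    beta = _build_beta(m, WHEAT_QTL)
    y = make_phenotype(X, beta, NOISE_SD, rng)
    return SimulatedDataset(
        X=X, y=y, design=design, beta_true=beta,
        regions=[(l - 1,) for l in qtl_loci],
        heritability=heritability(X, beta, y), X_complete=X,
    )
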