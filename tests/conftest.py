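import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_collinear_data():
    """A small collinear line-cross dataset with two planted effects."""
    import lassospace as ls

    X = ls.simulate_linecross_genotypes(60, 8, 0.1, seed=7)
    beta = np.array([3.0, 0, 0, 0, -2.0, 0, 0, 0])
    y = ls.make_phenotype(X, beta, 2.0, seed=8)
    return X, y, beta


@pytest.fixture(scope="session")
def tiny_draws():
    """A seeded PosteriorDraws object on a 20x3 design (short chain)."""
    import lassospace as ls

    rng = np.random.default_rng(5)
    X = ls.GenotypeMatrix(rng.choice((-1.0, 1.0), size=(20, 3)))
    y = ls.Phenotypes(X.values @ np.array([2.0, 0.0, -1.0]) + rng.normal(0, 1, 20))
    cfg = ls.SamplerConfig(
        lam=1.0, burn_in=500, thin=1, n_draws=1000, seed=9
    )
    return ls.gibbs_blasso(X, y, cfg)
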