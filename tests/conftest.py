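import numpy as np
import pytest

from biscale import ExpressionMatrix, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noiseless bi-scale cohort for fast structural tests."""
    cfg = SynthConfig(n_patients=8, patches_per_slide=6, n_spot_slides=3,
                      spots_per_slide=12, n_genes=6, embed_dim=8,
                      latent_dim=2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def counts_cohort():
    """Cohort with Poisson count sampling (exercises the count paths)."""
    cfg = SynthConfig(n_patients=4, patches_per_slide=5, n_spot_slides=2,
                      spots_per_slide=10, n_genes=12, embed_dim=8,
                      latent_dim=2, count_depth=5000.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def random_counts():
    rng = np.random.default_rng(42)

    def make(n_genes, n_samples, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        values = r.poisson(5.0, size=(n_genes, n_samples)).astype(float)
        return ExpressionMatrix(values,
                                [f"g{i:03d}" for i in range(n_genes)],
                                [f"s{i:03d}" for i in range(n_samples)],
                                "raw_counts")

    return make
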