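import numpy as np
import pytest

import barqtl as b


def random_profile(rng, length=None):
    """An arbitrary profile of iid uniform gray values (no bar structure)."""
    n = int(length if length is not None else rng.integers(30, 401))
    return b.IntensityProfile(
        values=rng.uniform(0, 255, n), scale_cm_per_px=0.01, individual_id="rand"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cross():
    """A fully-typed 3-linkage-group cross with one planted additive QTL."""
    spec = b.CrossSimSpec(
        lmap=b.make_grid_map(3, 20, 10.0),
        n_individuals=200,
        qtl=[b.PlantedQTL("LG2", 35.0, "pheno", a=0.7)],
        seed=11,
    )
    return b.simulate_f2_cross(spec)


@pytest.fixture(scope="session")
def small_probs(small_cross):
    return b.genotype_probabilities(small_cross, step_cM=1.0, error_rate=0.0)
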