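import numpy as np
import pytest

from mirstrat.simulate import PlantedPair, SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients, 4x4 universe, one near-deterministic planted pair.

    The association is deliberately strong (r = -0.99, hazard ratio 6)
    so that group membership is identifiable and the mechanics of every
    pipeline stage can be asserted sharply.
    """
    spec = SyntheticSpec(
        n_samples=60,
        n_genes=4,
        n_mirs=4,
        planted_pairs=(PlantedPair(0, 0, 0.5, -0.99, 6.0),),
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    return generate(SyntheticSpec(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
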