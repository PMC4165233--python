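import numpy as np
import pytest

from dendrofire.morphometrics import ElectrotonicConstants
from dendrofire.synthetic import TreeRecipe, fixture_suite, generate_tree


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def consts():
    return ElectrotonicConstants()


@pytest.fixture()
def random_trees():
    """A small bank of random binary basal trees (deterministic seeds)."""
    return [
        generate_tree(
            TreeRecipe(
                n_stems=2 + s % 3,
                bifurcation_prob=0.5,
                segment_length_mean=60.0,
                segment_length_sd=15.0,
                stem_diameter=1.0 + 0.1 * (s % 4),
                taper=0.85,
                max_depth=4,
                seed=s,
            )
        )
        for s in range(12)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
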