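import numpy as np
import pytest

from dendrocarbon.ringio import RingSeries
from dendrocarbon.synthetic import CohortConfig, SpeciesBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def constant_series():
    return RingSeries(
        tree_id="T1", radius_id="r1", widths=np.full(100, 1.5), last_year=2000
    )


@pytest.fixture
def small_cohort_config():
    """A 5-tree single-species cohort for fast end-to-end runs."""
    return CohortConfig(
        species_blocks=(
            SpeciesBlock(
                species="G_glabra",
                n_trees=5,
                age_range=(90, 150),
                diameter_range_cm=(40.0, 70.0),
                wood_density=0.72,
            ),
        ),
        radii_per_tree=4,
        seed=11,
    )
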