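import numpy as np
import pandas as pd
import pytest

from traitscape.ranges import build_stack
from traitscape.synthetic import (
    Landscape,
    PoolConfig,
    SpeciesPool,
    generate_landscape,
    generate_species_pool,
    grow_all_ranges,
)


@pytest.fixture(scope="session")
def landscape() -> Landscape:
    return generate_landscape(16, 16, seed=11)


@pytest.fixture(scope="session")
def pool(landscape) -> SpeciesPool:
    return generate_species_pool(12, landscape, PoolConfig(), seed=7)


@pytest.fixture(scope="session")
def stack(landscape, pool):
    extents = grow_all_ranges(pool, landscape, seed=13)
    return build_stack(extents, landscape.shape)


@pytest.fixture(scope="session")
def traits(pool) -> pd.DataFrame:
    return pool.traits()


def random_traits(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Small random but complete trait table for metric tests."""
    from traitscape.synthetic import DIET_CLASSES, MIGRATORY_CLASSES

    return pd.DataFrame(
        {
            "log_mass": rng.normal(3.5, 1.2, n),
            "log_genlength": rng.normal(1.0, 0.4, n),
            "migratory_class": rng.choice(MIGRATORY_CLASSES, n),
            "diet_class": rng.choice(DIET_CLASSES, n),
        },
        index=[f"sp{i:03d}" for i in range(n)],
    )
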