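import numpy as np
import pandas as pd
import pytest

from trophos.foodweb import (
    DetritusFateTable,
    DietMatrix,
    EcopathModel,
    FleetCatch,
    FunctionalGroup,
)
from trophos.synth import SyntheticSpec, make_toy_web


@pytest.fixture
def toy_chain() -> EcopathModel:
    """Three-level chain: producer (B=10, P/B=10) <- herbivore (B=2,
    C/B=25, P/B=5) <- carnivore (B=0.5, C/B=8, P/B=1); no catch.

    Hand evaluation of the master equation gives EE = 0.5, 0.4, 0."""
    groups = [
        FunctionalGroup(1, "P", "producer", biomass=10, pb=10),
        FunctionalGroup(2, "H", "consumer", biomass=2, pb=5, cb=25, ae=0.8),
        FunctionalGroup(3, "C", "consumer", biomass=0.5, pb=1, cb=8, ae=0.8),
    ]
    ids = [1, 2, 3]
    diet = pd.DataFrame(0.0, index=ids, columns=ids)
    diet.loc[1, 2] = 1.0
    diet.loc[2, 3] = 1.0
    return EcopathModel(
        groups,
        DietMatrix(diet),
        FleetCatch.empty(ids, []),
        fates=DetritusFateTable.uniform(ids),
    )


@pytest.fixture
def small_web() -> EcopathModel:
    return make_toy_web(SyntheticSpec(n_groups=8, seed=11))


@pytest.fixture
def web_spec() -> SyntheticSpec:
    return SyntheticSpec(n_groups=10, seed=3)
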