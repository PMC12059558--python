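import logging

import numpy as np
import pytest

from mycogrowth.community import hellinger_transform, select_dominant_taxa
from mycogrowth.model import build_design
from mycogrowth.synthetic import TruthConfig, generate_study

logging.getLogger("mycogrowth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """A quick 12-tree, 10-year study reused across tests."""
    return generate_study(
        TruthConfig(n_locations=4, trees_per_location=3, years=(2012, 2021), seed=3)
    )


@pytest.fixture(scope="session")
def mid_study():
    """30 trees x 20 years: big enough for meaningful inference checks."""
    return generate_study(
        TruthConfig(n_locations=6, trees_per_location=5, years=(2002, 2021), seed=7)
    )


@pytest.fixture(scope="session")
def mid_design(mid_study):
    hel = hellinger_transform(mid_study.community)
    sel = select_dominant_taxa(hel, k=7)
    return build_design(mid_study.growth_table, hel, sel)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
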