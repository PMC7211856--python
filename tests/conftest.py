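import numpy as np
import pytest

import corpusim as cs


@pytest.fixture(scope="session")
def records():
    return cs.load_species_table()


@pytest.fixture(scope="session")
def by_name(records):
    return {r.common_name: r for r in records}


@pytest.fixture(scope="session")
def cat_geometry(by_name):
    return cs.build_geometry(by_name["cat"])


@pytest.fixture(scope="session")
def materials():
    return cs.MaterialParams()


@pytest.fixture(scope="session")
def cat_pipeline(cat_geometry, materials):
    return cs.Pipeline(cat_geometry, materials)


@pytest.fixture(scope="session")
def fast_cfg():
    """Small frequency grid for unit-level pipeline tests."""
    return cs.TuningConfig(freq_grid=np.geomspace(20.0, 120.0, 5), scan_points=9)
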