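import numpy as np
import pytest

from ystrmps.catalog import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def survey(catalog):
    from ystrmps.fixtures import survey_profile

    return survey_profile(catalog)


@pytest.fixture(scope="session")
def reference_fixture(catalog):
    from ystrmps.fixtures import reference_tree_profile

    return reference_tree_profile(catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180712)
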