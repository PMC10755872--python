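import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from volindex import ContributionTable, calc_vol_batch, parse_smiles
from volindex.fixtures import builtin_fixture_suite


@pytest.fixture(scope="session")
def suite():
    return builtin_fixture_suite()


@pytest.fixture(scope="session")
def calculable_cases(suite):
    return [c for c in suite if not c.uncalculable]


@pytest.fixture(scope="session")
def table():
    return ContributionTable.default()


@pytest.fixture(scope="session")
def fixture_batch(suite):
    """Batch-result table over the whole builtin suite (incl. stubs)."""
    return calc_vol_batch([c.make_record() for c in suite])


PROPANE_MOLBLOCK = """propane
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  2  3  1  0  0  0  0
M  END
"""


@pytest.fixture
def propane_molblock():
    return PROPANE_MOLBLOCK
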