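import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rules():
    from paleoselect.coat_genetics import default_rules

    return default_rules()


@pytest.fixture(scope="session")
def grid():
    from paleoselect.cohort import default_period_grid

    return default_period_grid()


@pytest.fixture(scope="session")
def fixture_cohort():
    from paleoselect.synthetic_data import published_census_fixture

    return published_census_fixture()


@pytest.fixture()
def wildtype(rules):
    from paleoselect.coat_genetics import Genotype

    def make(**overrides):
        d = {n: 0 for n in rules.locus_names}
        d.update(overrides)
        return Genotype(d)

    return make


@pytest.fixture(scope="session")
def fixture_tsv(tmp_path_factory, fixture_cohort):
    from paleoselect.cohort import write_cohort

    path = tmp_path_factory.mktemp("data") / "fixture.tsv"
    write_cohort(fixture_cohort, path)
    return path
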