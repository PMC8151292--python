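import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from herdkeeper.fixtures import classic_pedigrees, random_pedigree
from herdkeeper.pedigree_io import topological_sort, validate_and_repair


def build(records):
    """Repair and sort a record list into a Pedigree."""
    repaired, _ = validate_and_repair(records)
    return topological_sort(repaired)


@pytest.fixture(scope="session")
def classics():
    return classic_pedigrees()


@pytest.fixture(scope="session")
def fullsib_pedigree(classics):
    return build(classics["fullsib"])


@pytest.fixture()
def random_pedigrees():
    def make(count=10, n=60, base_seed=0):
        return [build(random_pedigree(n, base_seed + s)) for s in range(count)]

    return make
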