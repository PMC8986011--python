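import numpy as np
import pytest

from tickhab import availability, load_counts, load_habitats, use_profile
from tickhab.datasets import (
    WET_AVAILABILITY_OVERRIDE,
    example_areas_path,
    example_counts_path,
)

HABITATS = ("Cocoa Crop", "Riparian Forest", "Star Grass Paddock", "King Grass Crop")

# published per-habitat stage counts (habitat order above)
DRY_COUNTS = {
    "all": (1498, 1606, 891, 2738),
    "adults": (20, 65, 20, 74),
    "nymph": (802, 795, 468, 1956),
    "larva": (676, 746, 403, 708),
}
WET_COUNTS = {
    "all": (37, 57, 99, 73),
    "adults": (37, 49, 22, 56),
    "nymph": (0, 8, 10, 4),
    "larva": (0, 0, 67, 13),
}


@pytest.fixture(scope="session")
def habitats():
    return load_habitats(example_areas_path())


@pytest.fixture(scope="session")
def counts(habitats):
    return load_counts(example_counts_path(), habitats)


@pytest.fixture(scope="session")
def area_p(habitats):
    return availability(habitats)


@pytest.fixture(scope="session")
def wet_override_p(habitats):
    from tickhab import AvailabilityVector

    return AvailabilityVector.explicit(WET_AVAILABILITY_OVERRIDE, habitats.names)


@pytest.fixture(scope="session")
def dry_total_profile(counts):
    return use_profile(counts, "all", "dry")


def profile_of(counts, group, season):
    return use_profile(counts, group, season)
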