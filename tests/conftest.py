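import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from patchdemes.records import OccupancySummary, PatchRecord


@pytest.fixture(scope="session")
def survey_summary() -> OccupancySummary:
    """The island-wide survey tallies: 101 of 400 patches occupied, 7 single."""
    return OccupancySummary(species="pwilidak", n_patches=400,
                            n_occupied=101, n_single=7)


@pytest.fixture
def small_records():
    return [
        PatchRecord(patch_id="P1", region="awak", forest_type="agroforest",
                    substrate_class="fruit", substrate_name="breadfruit",
                    elevation=40.0, species_counts={"pwilidak": 3}),
        PatchRecord(patch_id="P2", region="awak", forest_type="agroforest",
                    substrate_class="flower", elevation=55.0,
                    species_counts={"pwilidak": 1, "briggsae": 2}),
        PatchRecord(patch_id="P3", region="kolonia", forest_type="urban",
                    substrate_class="litter", elevation=5.0,
                    species_counts={}),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
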