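import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fragmetrics import (
    FragmentSizeDistribution,
    ReferenceProfile,
    ReferenceSet,
    average_fragment_length,
    synth_distribution,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def unimodal_dist() -> FragmentSizeDistribution:
    """Sonicated-DNA-like profile with modal length 300 bp."""
    return synth_distribution("unimodal", seed=7, mode_bp=300)


@pytest.fixture
def ladder_dist() -> FragmentSizeDistribution:
    """cfDNA-like mono-/di-/tri-nucleosome ladder."""
    return synth_distribution("nucleosome_ladder", seed=11, n_peaks=3)


def build_reference_set(modes=(150, 200, 280, 400, 600, 1000), sigma=0.4):
    """Reference panel of synthetic sonication profiles at given modes."""
    profiles = []
    for mode in modes:
        d = synth_distribution("unimodal", seed=mode, mode_bp=mode, sigma=sigma)
        profiles.append(
            ReferenceProfile(f"ref{mode}", d, average_fragment_length(d))
        )
    return ReferenceSet(profiles)


@pytest.fixture
def refset() -> ReferenceSet:
    return build_reference_set()
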