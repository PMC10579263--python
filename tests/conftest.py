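import numpy as np
import pytest

from hepaseg.backend import rules_from_profile
from hepaseg.synthetic import (
    FindingSpec,
    SynthProfile,
    default_profiles,
    generate_slide,
)


@pytest.fixture(scope="session")
def rules():
    """Colour rules matched to the default synthetic palette."""
    return rules_from_profile()


@pytest.fixture(scope="session")
def small_profile():
    """A sparse profile that fits a single 448x448 tile."""
    return SynthProfile(
        "mini",
        (
            FindingSpec("portal_area", (2, 2), (30, 50), "blob"),
            FindingSpec("necrosis", (1, 1), (60, 90), "blob"),
            FindingSpec("vacuolation", (2, 2), (20, 30), "blob"),
        ),
    )


@pytest.fixture(scope="session")
def small_slide(small_profile):
    """One deterministic 448x448 synthetic slide (a single tile)."""
    return generate_slide(small_profile, seed=11, height=448, width=448)


@pytest.fixture(scope="session")
def apap_slide():
    """A 5x5-tile APAP-profile slide (necrosis + infiltration burden)."""
    return generate_slide(default_profiles()["APAP"], seed=3, height=2240, width=2240)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
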