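import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motif3d.fixtures import FixtureRecipe, PlantedMotif, make_chain, triad_template

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


MINIMAL_ALA = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.182  -5.123  1.00  0.00           C
ATOM      4  O   ALA A   1      12.412   8.304  -5.553  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_ala_text():
    return MINIMAL_ALA


@pytest.fixture(scope="session")
def triad_fixture():
    """A 60-residue synthetic chain with one planted His/Asp/Ser motif."""
    return make_chain(
        FixtureRecipe(
            n_residues=60,
            planted=(PlantedMotif(triad_template(), copies=1, noise_sigma=0.0),),
            seed=3,
            structure_id="triad60",
        )
    )


@pytest.fixture(scope="session")
def two_copy_fixture():
    """An 80-residue chain with two noise-free copies of the triad motif."""
    return make_chain(
        FixtureRecipe(
            n_residues=80,
            planted=(PlantedMotif(triad_template(), copies=2, noise_sigma=0.0),),
            seed=11,
            structure_id="triad2x",
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
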