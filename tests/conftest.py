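import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture(scope="session")
def recovery_fixture():
    """One planted druggable site, 300 frames, bulk noise (seed 11)."""
    from probesite.synthetic_fixtures import build_fixture, recovery_config

    return build_fixture(recovery_config(n_loci=1, n_frames=300), seed=11)


@pytest.fixture(scope="session")
def recovery_superposed(recovery_fixture):
    from probesite.trajectory_io import superpose

    return superpose(recovery_fixture.to_ensemble(),
                     recovery_fixture.reference_structure())


@pytest.fixture(scope="session")
def random_fixture():
    """50-frame, ~500-protein-atom, 30-probe fixture with no planted signal."""
    from probesite.synthetic_fixtures import build_fixture, random_config

    return build_fixture(random_config(n_frames=50, n_residues=50, n_probes=30),
                         seed=5)


@pytest.fixture(scope="session")
def random_superposed(random_fixture):
    from probesite.trajectory_io import superpose

    return superpose(random_fixture.to_ensemble(),
                     random_fixture.reference_structure())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
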