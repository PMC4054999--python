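import pytest

import woundstereo as ws
from woundstereo.pipeline import StudyConfig, run_study
from woundstereo.validation import anisotropy_comparison, recovery_experiment


@pytest.fixture(scope="session")
def recovery_result():
    """Full isotropic recovery experiment at the standard validation conditions."""
    return recovery_experiment(seed=0)


@pytest.fixture(scope="session")
def anisotropy_result():
    """Cycloid vs straight-line length bias on axially anisotropic tissue."""
    return anisotropy_comparison(seed=2024)


@pytest.fixture(scope="session")
def rendered_study():
    """A four-arm, n=8 synthetic study rendered into section images."""
    return ws.generate_study(n_per_group=8, seed=601, render=True)


@pytest.fixture(scope="session")
def rendered_study_results(rendered_study):
    report, per_wound = run_study(rendered_study, StudyConfig(seed=11))
    return rendered_study, report, per_wound


@pytest.fixture(scope="session")
def small_tissue():
    """A modest isotropic network reused by sectioning tests."""
    tis = ws.generate_network(8000.0, 2.0, box=(80.0, 80.0, 80.0), segment_length=40.0, seed=3)
    return ws.generate_cell_field(tis, 0.10, cell_radius=5.0, seed=4)
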