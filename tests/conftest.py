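import warnings

import pytest

from turtleharvest.synth import SynthConfig, generate_reports
from turtleharvest.traits import aggregate_species


@pytest.fixture(scope="session")
def default_reports():
    reports, truth = generate_reports(SynthConfig(seed=0))
    return reports, truth


@pytest.fixture(scope="session")
def default_species(default_reports):
    reports, _ = default_reports
    return aggregate_species(reports)


@pytest.fixture(autouse=True)
def _quiet_unseen_family_warnings():
    # predict_traits warns when a family is absent from a trait's training
    # subset; that is expected under per-trait missingness.
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="families unseen in training"
        )
        yield
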