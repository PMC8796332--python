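import pytest

from wisn_national.national import panel_frame
from wisn_national.synthetic import (
    SimulationConfig,
    generate_facility_panel,
    standards_for,
)
from wisn_national.wisn import LeavePolicy, compute_panel


@pytest.fixture(scope="session")
def study_config():
    """Small study-condition panel: 5 states x 8 years x 8 combos,
    3 facilities per state and centre type."""
    return SimulationConfig(facilities_per_state_centretype=3, seed=42)


@pytest.fixture(scope="session")
def study_records(study_config):
    return generate_facility_panel(study_config)


@pytest.fixture(scope="session")
def study_results(study_config, study_records):
    return compute_panel(
        study_records, standards_for(study_config), study_config.leave_policy
    )


@pytest.fixture(scope="session")
def study_panel(study_results):
    return panel_frame(study_results)


@pytest.fixture(scope="session")
def policy():
    return LeavePolicy()
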