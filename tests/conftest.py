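import pytest

from lrsahs import DetectorConfig, SynthParams, generate_cohort, generate_recording


@pytest.fixture
def cfg():
    return DetectorConfig()


@pytest.fixture(scope="session")
def night():
    """One default 8-h synthetic night (seeded)."""
    return generate_recording(SynthParams(seed=42))


@pytest.fixture(scope="session")
def short_night():
    """A 1-h night for cheap pipeline-level tests."""
    return generate_recording(
        SynthParams(seed=3, duration_h=1.0, n_apnea=4, n_hypopnea=2, n_flow_artifact=3)
    )


@pytest.fixture(scope="session")
def cohort10():
    """Ten synthetic nights under default calibration (seeded)."""
    return generate_cohort(10, seed=7)
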