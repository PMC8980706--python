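import pytest

import lcdetect as lc


@pytest.fixture(scope="session")
def default_config():
    return lc.PipelineConfig()


@pytest.fixture(scope="session")
def default_records(default_config):
    """One simulated run of the full 20-reader study (1 invalid response)."""
    return lc.simulate_trials(default_config)


@pytest.fixture(scope="session")
def cleaned_records(default_records):
    records, _ = lc.clean_responses(default_records)
    return records


@pytest.fixture()
def small_design():
    """2 readers x 2 doses x 2 algorithms x 1 lesion type x 1 scan x 1 slice."""
    return lc.StudyDesign(
        readers=[
            lc.Reader(id="R1", group="radiologist"),
            lc.Reader(id="R2", group="non-radiologist"),
        ],
        doses=[5.0, 10.0],
        algorithms=["FBP", "DLH"],
        lesion_types=["4 mm hyperdense"],
        scans_per_dose=1,
        signal_present_slices_per_scan=1,
    )
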