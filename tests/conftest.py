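import pytest

from cleaveqc.io_formats import ProteinRecord, RunConfig
from cleaveqc.synthetic_data import SimulationConfig


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def small_proteins():
    return {
        "P1": ProteinRecord("P1", "MKAVRGAGAGKLLWK"),
        "P2": ProteinRecord("P2", "GAGAG"),
    }


@pytest.fixture
def fast_sim_config():
    """A small, quick simulation: one untreated and one treated sample."""
    return SimulationConfig(
        n_proteins=30,
        protein_length_range=(60, 120),
        protease_activity={"untx": 0.3, "dfp": 0.3},
        dfp_samples=frozenset({"dfp"}),
        detectability_dropout=0.0,
        intensity_noise_cv=0.0,
        seed=101,
    )
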