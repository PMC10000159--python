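import pytest

from ethochain import (ChainDefinition, SimulationConfig, event_log_from_rows,
                       load_default_ethogram)


@pytest.fixture(scope="session")
def ethogram():
    return load_default_ethogram()


@pytest.fixture
def chain_def():
    return ChainDefinition()


@pytest.fixture
def full_chain_log():
    """One session containing a single fully completed social-reward chain."""
    return event_log_from_rows([
        ("s1", 0.0, "EU1", "Nobj"),
        ("s1", 5.0, "EU2", "GrpFrmt"),
        ("s1", 12.0, "EU3", "Greet"),
        ("s1", 20.0, "EU2", "LickSn"),
        ("s1", 27.0, "EU4", "C.SubmBhv"),
        ("s1", 33.0, "EU2", "LeaveTgh"),
    ])


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=123)
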