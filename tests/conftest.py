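import pytest
from hypothesis import settings

from munchflow import load_preset, run

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def r1_wet():
    """Default 12-h run: lowest resistance, wet soil, unregulated loading."""
    params = load_preset("R1")
    traj, outcome = run(params)
    return params, traj, outcome


@pytest.fixture(scope="session")
def r1_dry():
    params = load_preset("R1", psi_s=-1.0)
    traj, outcome = run(params)
    return params, traj, outcome


@pytest.fixture(scope="session")
def default_params():
    return load_preset("default")
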