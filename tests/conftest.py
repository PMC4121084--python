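import pytest

from zgaprof import SimConfig, StageDesign, simulate_study


@pytest.fixture(scope="session")
def human_design() -> StageDesign:
    return StageDesign(["MII", "4-cell", "8-cell", "blastocyst"], 3, species="human")


@pytest.fixture(scope="session")
def mouse_design() -> StageDesign:
    return StageDesign(["MII", "1-cell", "2-cell", "8-cell"], 3, species="mouse")


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared by read-only tests."""
    return simulate_study(SimConfig(seed=11, n_per_archetype=25))
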