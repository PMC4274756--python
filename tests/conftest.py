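import pytest

from qtlprio import AnalysisParameters, run_prioritization, simulate
from qtlprio.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_sim():
    """The default planted synthetic instance, seed 1."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Pipeline result on the default planted instance, default parameters."""
    return run_prioritization(
        default_sim.genome,
        default_sim.compendium,
        default_sim.annotation,
        AnalysisParameters(),
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_sim):
    """The default instance written out as input files."""
    from qtlprio import write_fixture

    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(default_sim, directory)
    return directory
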