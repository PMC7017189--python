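import pytest

from fgfr2axis import SimulationConfig, simulate_cohort, run_on_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_pairs=20, n_unpaired_tumors=180, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config, tmp_path_factory):
    return simulate_cohort(small_config, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return run_on_cohort(small_cohort)
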