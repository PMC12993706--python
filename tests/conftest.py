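"""Shared fixtures: synthetic scenarios and pipeline runs reused across
test modules (session-scoped, since generation dominates test runtime)."""

import pytest

import ecoforcing as ef
from ecoforcing import radiative_forcing as rf


@pytest.fixture(scope="session")
def default_config():
    return ef.AnalysisConfig()


@pytest.fixture(scope="session")
def kernels():
    return rf.synthetic_kernel_ensemble(seed=0)


@pytest.fixture(scope="session")
def noisy_scenario():
    """Two study years with the default noise, gaps and rain structure."""
    return ef.ScenarioSpec(seed=7)


@pytest.fixture(scope="session")
def noisy_records(noisy_scenario):
    return ef.generate_halfhourly(noisy_scenario)


@pytest.fixture(scope="session")
def noisy_results(noisy_scenario, noisy_records, default_config, kernels):
    cal = ef.synthetic_towers.calendar_for(noisy_scenario)
    return ef.run_pipeline(noisy_records, default_config, cal, kernels)


@pytest.fixture(scope="session")
def closed_scenario():
    """Three noise-free years with full energy-balance closure."""
    spec = ef.ScenarioSpec(seed=3).zero_noise(closure=1.0)
    spec.n_years = 3
    return spec


@pytest.fixture(scope="session")
def closed_results(closed_scenario, default_config, kernels):
    records = ef.generate_halfhourly(closed_scenario)
    cal = ef.synthetic_towers.calendar_for(closed_scenario)
    return ef.run_pipeline(records, default_config, cal, kernels)
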