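import warnings

import pytest

import cpetdx as cd
from cpetdx.simulate import HEART_FAILURE, METABOLIC_SYNDROME, Protocol


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def hf_noiseless():
    """Zero-noise heart-failure patient (peak 14 mL/min/kg, AT at 45%)."""
    import dataclasses
    arch = dataclasses.replace(HEART_FAILURE, noise_sd_per_channel=0.0)
    return cd.simulate_patient(arch, seed=11)


@pytest.fixture(scope="session")
def ms_noiseless():
    import dataclasses
    arch = dataclasses.replace(METABOLIC_SYNDROME, noise_sd_per_channel=0.0)
    return cd.simulate_patient(arch, seed=12)


@pytest.fixture(scope="session")
def hf_noisy():
    return cd.simulate_patient(HEART_FAILURE, seed=21)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 5+5 cohort for unit-level pipeline tests."""
    return cd.simulate_cohort(5, seed=3)


@pytest.fixture(scope="session")
def benchmark_cohort():
    """The 15+15 study-condition cohort (well-separated archetypes)."""
    return cd.simulate_cohort(15, seed=7)


@pytest.fixture(scope="session")
def benchmark_table(benchmark_cohort):
    """One shared 5-fold benchmark run over all five methods (the CNN
    dominates the runtime, so the run is computed once per session)."""
    return cd.run_benchmark(benchmark_cohort, k=5, seed=0)


@pytest.fixture(autouse=True)
def _quiet_ae_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*autoencoder trained on only.*")
        yield
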