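import pytest
from hypothesis import HealthCheck, settings

from virtrial import qsp
from virtrial.definitions import load_study_drugs
from virtrial.synthetic import (
    generate_disease_embedding,
    generate_network,
    generate_restrictions,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_drugs():
    return load_study_drugs()


@pytest.fixture(scope="session")
def small_network(study_drugs):
    include = sorted({g for d in study_drugs.values() for g in d.target_genes})
    return generate_network(40, 0.08, seed=1, include=include)


@pytest.fixture(scope="session")
def disease(small_network):
    return generate_disease_embedding(small_network, (4, 4, 4, 4), seed=2)


@pytest.fixture(scope="session")
def restrictions(small_network, disease, study_drugs):
    return generate_restrictions(
        small_network,
        disease,
        [(study_drugs["vLDX"], 0.6), (study_drugs["vMPH"], 0.45)],
    )


@pytest.fixture(scope="session")
def ensemble(small_network, restrictions):
    return qsp.train_ensemble(
        small_network, restrictions, n_solutions=5, seed=3, iterations=200
    )
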