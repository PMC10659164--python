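import pytest

from biobank_dq import catalog as cat
from biobank_dq import synthetic as syn
from biobank_dq.engine import evaluate_catalog
from biobank_dq.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def prereview_catalog():
    return cat.build_prereview_catalog()


@pytest.fixture(scope="session")
def final_cat():
    return cat.final_catalog()


@pytest.fixture(scope="session")
def small_config():
    return syn.GeneratorConfig(
        institutions=tuple("ABCD"), records_per_institution=150
    )


@pytest.fixture(scope="session")
def clean_network(small_config):
    return syn.generate_clean(small_config, seed=11)


@pytest.fixture(scope="session")
def mixed_model():
    return syn.ErrorModel(
        null_rate={"A": 0.05, "B": 0.02, "C": 0.0, "D": 0.08},
        date_malform_rate={"A": 0.03, "B": 0.0, "C": 0.0, "D": 0.05},
        code_malform_rate={"A": 0.02, "B": 0.04, "C": 0.0, "D": 0.03},
        unit_error_rate={"A": 0.02, "B": 0.01, "C": 0.0, "D": 0.02},
        logic_error_rate={"A": 0.02, "B": 0.03, "C": 0.0, "D": 0.04},
        duplicate_rate={"A": 0.01, "B": 0.02, "C": 0.0, "D": 0.01},
    )


@pytest.fixture(scope="session")
def corrupted_network(clean_network, mixed_model):
    return syn.inject_errors(clean_network, mixed_model, seed=12)


@pytest.fixture(scope="session")
def violations(corrupted_network, final_cat):
    datasets, _ = corrupted_network
    return evaluate_catalog(final_cat, datasets)
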