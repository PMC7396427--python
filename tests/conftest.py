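import pytest
from hypothesis import HealthCheck, settings

from mitocomp import datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def focal_annotation():
    return datasets.load_focal_annotation()


@pytest.fixture(scope="session")
def focal_counts():
    return datasets.load_focal_codon_counts()


@pytest.fixture(scope="session")
def focal_codon_table():
    return datasets.load_focal_codon_table()


@pytest.fixture(scope="session")
def focal_order():
    return datasets.load_focal_gene_order()
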