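import pytest
from hypothesis import HealthCheck, settings

from phenomine import GeneratorConfig, generate_corpus, smoking_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dhr_config() -> GeneratorConfig:
    """Down-scaled drug-hypersensitivity corpus: short docs, few per class."""
    return GeneratorConfig(
        seed=11,
        n_per_label={"SJS": 8, "DIHS": 8, "AS": 6, "EB": 6, "NEG": 20},
        doc_length_mean=300.0,
        doc_length_min=50,
        doc_length_max=3000,
    )


@pytest.fixture(scope="session")
def small_dhr_corpus(small_dhr_config):
    return generate_corpus(small_dhr_config)


@pytest.fixture(scope="session")
def small_smoking_corpus():
    return generate_corpus(
        smoking_config(
            seed=13,
            n_per_label={"PAST": 6, "CURRENT": 6, "NON": 8, "UNKNOWN": 16},
            doc_length_mean=120.0,
            doc_length_min=30,
            doc_length_max=1000,
        )
    )
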