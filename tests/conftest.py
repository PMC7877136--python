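import pytest

from interrai_ci import RuleCatalogue, SyntheticConfig, generate_paired_dataset


@pytest.fixture(scope="session")
def catalogue():
    return RuleCatalogue.default()


@pytest.fixture(scope="session")
def dictionary(catalogue):
    return catalogue.dictionary


@pytest.fixture(scope="session")
def perfect_pair():
    """Small paired dataset with perfect index/checklist agreement."""
    config = SyntheticConfig(
        n_subjects=200,
        agreement={rid: 1.0 for rid in RuleCatalogue.default().rule_ids()},
        seed=42,
    )
    return generate_paired_dataset(config)


@pytest.fixture(scope="session")
def default_pair():
    """Paired dataset under the generator's default (study-like) conditions."""
    return generate_paired_dataset(SyntheticConfig(seed=97))
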