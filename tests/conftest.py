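import pytest

from crisischat.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def default_corpus():
    """Default study conditions at a size where prevalence, demographic and
    baseline-score recovery have usable Monte-Carlo error."""
    return generate_corpus(GeneratorConfig(n_sessions=20_000, seed=808))


@pytest.fixture(scope="session")
def flag_corpus():
    """SI-heavy corpus (equal passive/active visit prevalence raised to 9%)
    so latency, ordering and referral statistics get thousands of SI
    sessions; the flag/latency/ordering configuration stays at defaults."""
    return generate_corpus(
        GeneratorConfig(
            n_sessions=10_000, seed=424, prevalence_passive=0.09, prevalence_active=0.09
        )
    )


@pytest.fixture(scope="session")
def si_corpus():
    """Mid-size corpus with boosted passive prevalence for matching,
    phrase-mining and pipeline tests."""
    return generate_corpus(
        GeneratorConfig(
            n_sessions=3_000, seed=99, prevalence_passive=0.06, prevalence_active=0.02
        )
    )


@pytest.fixture()
def tiny_config():
    return GeneratorConfig(n_sessions=60, seed=7)
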